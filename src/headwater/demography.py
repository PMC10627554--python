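"""Demographic scenario models for coastal-basin headwater-capture histories.

A :class:`ScenarioModel` describes a rooted divergence history over a set of
populations: merge events (viewed backward in time, a daughter population's
lineages join their source), piecewise-constant effective sizes, founder
bottlenecks after each colonization, and priors over the named parameters.

Six canonical scenarios for the five-basin system (Paraguacu, Jequirica,
Almas, Contas, Almada) are built by :func:`build_capture_scenario`:

* scenarios 1 / 2 — a single simultaneous radiation out of Paraguacu (1) or
  Contas (2);
* scenarios 3 / 5 — staggered, sequential headwater captures with Paraguacu
  (3) or Contas (5) as the initial source;
* scenarios 4 / 6 — one initial capture between Paraguacu and Contas
  followed by one simultaneous colonization of the three remaining basins.

Every daughter basin is founded through a bottleneck of size ``Nb_<basin>``
lasting ``db`` generations, after which it expands to its present size
``N_<basin>``.  Effective sizes are counted in diploid individuals, so the
coalescence rate for *j* lineages is j(j-1)/(4N) per generation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import yaml

__all__ = [
    "PopulationSpec",
    "DemographicEvent",
    "ParameterPrior",
    "ScenarioModel",
    "ParameterDraw",
    "CompiledDemography",
    "BASIN_NAMES",
    "BASIN_SAMPLE_SIZES",
    "default_priors",
    "build_capture_scenario",
    "all_capture_scenarios",
    "draw_parameters",
    "compile_demography",
    "scenarios_to_yaml",
    "scenarios_from_yaml",
]

#: Basin labels in canonical order (fixes summary-vector and VCF layouts).
BASIN_NAMES = ("Paraguacu", "Jequirica", "Almas", "Contas", "Almada")

#: Diploid individuals sampled per basin in the study design.
BASIN_SAMPLE_SIZES = {
    "Paraguacu": 6,
    "Jequirica": 5,
    "Almas": 4,
    "Contas": 9,
    "Almada": 9,
}


class ConfigurationError(ValueError):
    """Raised when a scenario definition is internally inconsistent."""


@dataclass(frozen=True)
class PopulationSpec:
    """A sampled population with its present-day effective size parameter."""

    name: str
    n_diploid_samples: int
    ne_current: str  # name of a size parameter

    def __post_init__(self) -> None:
        if self.n_diploid_samples < 0:
            raise ConfigurationError(
                f"negative sample size for population {self.name!r}"
            )


@dataclass(frozen=True)
class DemographicEvent:
    """A merge or size-change event at a (parameterized) time.

    ``kind='merge'``: backward in time, all lineages of ``source_pop`` move
    into ``dest_pop`` at ``time_param`` generations before present.
    ``kind='size_change'``: ``source_pop``'s size becomes ``new_size_param``
    for all older times (until another size change).
    """

    kind: str
    time_param: str
    source_pop: str
    dest_pop: str | None = None
    new_size_param: str | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("merge", "size_change"):
            raise ConfigurationError(f"unknown event kind {self.kind!r}")
        if self.kind == "merge" and self.dest_pop is None:
            raise ConfigurationError("merge event needs dest_pop")
        if self.kind == "size_change" and self.new_size_param is None:
            raise ConfigurationError("size_change event needs new_size_param")


@dataclass(frozen=True)
class ParameterPrior:
    """Uniform or log-uniform prior over a positive scalar parameter.

    Times are in generations before present; sizes in diploid individuals.
    """

    name: str
    distribution: str  # 'uniform' | 'log-uniform'
    lower: float
    upper: float

    def __post_init__(self) -> None:
        if self.distribution not in ("uniform", "log-uniform"):
            raise ConfigurationError(
                f"unsupported prior family {self.distribution!r}"
            )
        if not (0 < self.lower <= self.upper):
            raise ConfigurationError(
                f"prior {self.name!r}: need 0 < lower <= upper"
            )

    def sample(self, rng: np.random.Generator, size: int | None = None):
        if self.distribution == "uniform":
            return rng.uniform(self.lower, self.upper, size)
        lo, hi = np.log(self.lower), np.log(self.upper)
        return np.exp(rng.uniform(lo, hi, size))


@dataclass(frozen=True)
class Bottleneck:
    """Founder bottleneck: the population has size ``bottleneck_size_param``
    for ``duration_param`` generations following its founding at
    ``founding_time_param`` (ages in [t - db, t] backward in time); if
    db >= t the bottleneck spans the whole post-founding period."""

    population: str
    founding_time_param: str
    duration_param: str
    bottleneck_size_param: str


@dataclass
class ScenarioModel:
    """A complete demographic scenario: topology, sizes, priors, constraints.

    ``constraints`` is a list of ``(a, b)`` pairs meaning parameter
    ``a`` must exceed parameter ``b`` in every valid draw.
    """

    scenario_id: int
    populations: list[PopulationSpec]
    events: list[DemographicEvent]
    priors: list[ParameterPrior]
    constraints: list[tuple[str, str]] = field(default_factory=list)
    bottlenecks: list[Bottleneck] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.validate()

    # -- consistency -------------------------------------------------------

    def validate(self) -> None:
        pop_names = [p.name for p in self.populations]
        if len(set(pop_names)) != len(pop_names):
            raise ConfigurationError("duplicate population names")
        prior_names = {p.name for p in self.priors}

        def need(param: str) -> None:
            if param not in prior_names:
                raise ConfigurationError(
                    f"scenario {self.scenario_id}: parameter {param!r} "
                    "has no prior"
                )

        for pop in self.populations:
            need(pop.ne_current)
        merged_once: set[str] = set()
        for ev in self.events:
            if ev.source_pop not in pop_names or (
                ev.kind == "merge" and ev.dest_pop not in pop_names
            ):
                raise ConfigurationError(
                    f"event references unknown population: {ev}"
                )
            need(ev.time_param)
            if ev.kind == "merge":
                if ev.source_pop in merged_once:
                    raise ConfigurationError(
                        f"population {ev.source_pop!r} merges more than once"
                    )
                merged_once.add(ev.source_pop)
            else:
                need(ev.new_size_param)
        n_merges = sum(ev.kind == "merge" for ev in self.events)
        if len(pop_names) > 1 and n_merges != len(pop_names) - 1:
            raise ConfigurationError(
                f"{n_merges} merges cannot join {len(pop_names)} populations "
                "into one ancestor"
            )
        self._check_tree(pop_names)
        founded = {
            ev.source_pop: ev.time_param for ev in self.events
            if ev.kind == "merge"
        }
        for b in self.bottlenecks:
            for p in (b.founding_time_param, b.duration_param,
                      b.bottleneck_size_param):
                need(p)
            if founded.get(b.population) != b.founding_time_param:
                raise ConfigurationError(
                    f"bottleneck on {b.population!r} is not anchored to the "
                    "merge event founding that population"
                )
        for a, b_ in self.constraints:
            need(a)
            need(b_)
        self._check_acyclic_constraints()

    def _check_tree(self, pop_names: list[str]) -> None:
        # every lineage must reach a common ancestor: follow merge edges
        dest = {
            ev.source_pop: ev.dest_pop for ev in self.events
            if ev.kind == "merge"
        }
        roots = set()
        for name in pop_names:
            seen = set()
            cur = name
            while cur in dest:
                if cur in seen:
                    raise ConfigurationError("merge events form a cycle")
                seen.add(cur)
                cur = dest[cur]
            roots.add(cur)
        if len(pop_names) > 1 and len(roots) != 1:
            raise ConfigurationError(
                f"merge events leave {len(roots)} disconnected ancestors"
            )

    def _check_acyclic_constraints(self) -> None:
        edges = set(self.constraints)
        order = {}
        for a, b in edges:
            order.setdefault(a, set()).add(b)

        def reaches(x: str, y: str, seen: set) -> bool:
            if x == y:
                return True
            seen.add(x)
            return any(
                reaches(z, y, seen) for z in order.get(x, ()) if z not in seen
            )

        for a, b in edges:
            if reaches(b, a, set()):
                raise ConfigurationError(
                    f"constraint cycle involving {a!r} > {b!r}"
                )

    # -- helpers -----------------------------------------------------------

    @property
    def parameter_names(self) -> list[str]:
        return [p.name for p in self.priors]

    def prior(self, name: str) -> ParameterPrior:
        for p in self.priors:
            if p.name == name:
                return p
        raise KeyError(name)

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "scenario_id": self.scenario_id,
            "populations": [
                {"name": p.name, "n_diploid_samples": p.n_diploid_samples,
                 "ne_current": p.ne_current}
                for p in self.populations
            ],
            "events": [
                {k: v for k, v in {
                    "kind": ev.kind, "time_param": ev.time_param,
                    "source_pop": ev.source_pop, "dest_pop": ev.dest_pop,
                    "new_size_param": ev.new_size_param,
                }.items() if v is not None}
                for ev in self.events
            ],
            "priors": [
                {"name": p.name, "distribution": p.distribution,
                 "lower": float(p.lower), "upper": float(p.upper)}
                for p in self.priors
            ],
            "constraints": [list(c) for c in self.constraints],
            "bottlenecks": [
                {"population": b.population,
                 "founding_time_param": b.founding_time_param,
                 "duration_param": b.duration_param,
                 "bottleneck_size_param": b.bottleneck_size_param}
                for b in self.bottlenecks
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ScenarioModel":
        return cls(
            scenario_id=int(d["scenario_id"]),
            populations=[PopulationSpec(**p) for p in d["populations"]],
            events=[DemographicEvent(**e) for e in d["events"]],
            priors=[ParameterPrior(**p) for p in d["priors"]],
            constraints=[tuple(c) for c in d.get("constraints", [])],
            bottlenecks=[Bottleneck(**b) for b in d.get("bottlenecks", [])],
        )


@dataclass(frozen=True)
class ParameterDraw:
    """One concrete instantiation of a scenario's parameters."""

    scenario_id: int
    values: dict[str, float]

    def __getitem__(self, name: str) -> float:
        return self.values[name]


# ---------------------------------------------------------------------------
# canonical six-scenario suite
# ---------------------------------------------------------------------------

def default_priors(time_names: tuple[str, ...]) -> list[ParameterPrior]:
    """Default priors: divergence times uniform on [1e4, 3e6] generations,
    present sizes N uniform on [1e3, 1e5] diploids, founder bottleneck sizes
    Nb uniform on [10, 1e3], bottleneck duration db uniform on [10, 1e3].
    """
    priors = [
        ParameterPrior(t, "uniform", 1e4, 3e6) for t in time_names
    ]
    priors += [
        ParameterPrior(f"N_{b}", "uniform", 1e3, 1e5) for b in BASIN_NAMES
    ]
    priors += [
        ParameterPrior(f"Nb_{b}", "uniform", 10.0, 1e3) for b in BASIN_NAMES
    ]
    priors.append(ParameterPrior("db", "uniform", 10.0, 1e3))
    return priors


def _scenario_edges(k: int) -> tuple[list[tuple[str, str, str]],
                                     list[tuple[str, str]]]:
    """(source, daughter, time_param) merge edges and ordering constraints."""
    P, J, A, C, M = BASIN_NAMES  # M = Almada
    if k == 1:
        edges = [(P, C, "t1"), (P, M, "t1"), (P, J, "t1"), (P, A, "t1")]
        cons: list[tuple[str, str]] = []
    elif k == 2:
        edges = [(C, P, "t1"), (C, M, "t1"), (C, J, "t1"), (C, A, "t1")]
        cons = []
    elif k == 3:
        edges = [(P, C, "t1"), (C, M, "t2"), (P, J, "t3"), (J, A, "t4")]
        cons = [("t1", "t2"), ("t3", "t4"), ("t1", "t3")]
    elif k == 4:
        edges = [(P, C, "t1"), (P, J, "t2"), (P, A, "t2"), (C, M, "t2")]
        cons = [("t1", "t2")]
    elif k == 5:
        edges = [(C, P, "t1"), (P, M, "t2"), (C, J, "t3"), (J, A, "t4")]
        cons = [("t1", "t2"), ("t3", "t4"), ("t1", "t3")]
    elif k == 6:
        edges = [(C, P, "t1"), (C, J, "t2"), (C, A, "t2"), (P, M, "t2")]
        cons = [("t1", "t2")]
    else:
        raise ConfigurationError(f"unknown scenario id {k}; expected 1..6")
    return edges, cons


def build_capture_scenario(
    k: int,
    priors: list[ParameterPrior] | None = None,
    sample_sizes: dict[str, int] | None = None,
) -> ScenarioModel:
    """Build one of the six canonical headwater-capture scenarios.

    Parameters
    ----------
    k
        Scenario id in 1..6 (see module docstring for the topologies).
    priors
        Priors covering every parameter the scenario uses; defaults to
        :func:`default_priors`.
    sample_sizes
        Diploid samples per basin; defaults to the 6/5/4/9/9 study design.
    """
    edges, cons = _scenario_edges(k)
    time_names = tuple(dict.fromkeys(t for _, _, t in edges))
    if priors is None:
        priors = default_priors(time_names)
    sizes = dict(BASIN_SAMPLE_SIZES)
    if sample_sizes:
        sizes.update(sample_sizes)
    prior_names = {p.name for p in priors}
    needed = set(time_names) | {f"N_{b}" for b in BASIN_NAMES} | {"db"}
    needed |= {f"Nb_{d}" for _, d, _ in edges}
    missing = sorted(needed - prior_names)
    if missing:
        raise ConfigurationError(
            f"scenario {k}: missing priors for {', '.join(missing)}"
        )
    pops = [
        PopulationSpec(b, sizes[b], f"N_{b}") for b in BASIN_NAMES
    ]
    events = [
        DemographicEvent("merge", t, source_pop=d, dest_pop=s)
        for s, d, t in edges
    ]
    bottlenecks = [
        Bottleneck(d, t, "db", f"Nb_{d}") for _, d, t in edges
    ]
    used = needed
    return ScenarioModel(
        scenario_id=k,
        populations=pops,
        events=events,
        priors=[p for p in priors if p.name in used],
        constraints=cons,
        bottlenecks=bottlenecks,
    )


def all_capture_scenarios(
    priors: list[ParameterPrior] | None = None,
) -> list[ScenarioModel]:
    return [build_capture_scenario(k, priors) for k in range(1, 7)]


# ---------------------------------------------------------------------------
# prior sampling
# ---------------------------------------------------------------------------

def draw_parameters(
    model: ScenarioModel,
    seed: int | np.random.Generator,
    max_redraws: int = 10_000,
) -> ParameterDraw:
    """Draw one parameter set from the scenario's priors.

    Draws violating any ordering constraint are rejected and redrawn; the
    result is deterministic for a fixed integer seed.
    """
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    for _ in range(max_redraws):
        values = {p.name: float(p.sample(rng)) for p in model.priors}
        if all(values[a] > values[b] for a, b in model.constraints):
            return ParameterDraw(model.scenario_id, values)
    raise ConfigurationError(
        f"scenario {model.scenario_id}: constraints unsatisfied after "
        f"{max_redraws} redraws"
    )


# ---------------------------------------------------------------------------
# compilation to the flat event encoding used by the simulation kernels
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CompiledDemography:
    """Flat, array-based encoding of one scenario instantiation.

    Populations are indexed in ``pop_names`` order; events are sorted by
    time.  ``event_kinds``: 0 = size change of ``event_pop_a`` to
    ``event_sizes``; 1 = lineages of ``event_pop_a`` move to ``event_pop_b``.
    """

    pop_names: tuple[str, ...]
    sample_copies: np.ndarray   # gene copies per population (int64)
    init_sizes: np.ndarray      # diploid size at time 0 (float64)
    event_times: np.ndarray
    event_kinds: np.ndarray
    event_pop_a: np.ndarray
    event_pop_b: np.ndarray
    event_sizes: np.ndarray

    @property
    def n_copies(self) -> int:
        return int(self.sample_copies.sum())


def compile_demography(
    model: ScenarioModel, draw: ParameterDraw
) -> CompiledDemography:
    """Resolve a scenario + draw into the flat encoding the kernels consume."""
    if draw.scenario_id != model.scenario_id:
        raise ConfigurationError("draw does not belong to this scenario")
    v = draw.values
    idx = {p.name: i for i, p in enumerate(model.populations)}
    npop = len(model.populations)
    init = np.array([v[p.ne_current] for p in model.populations])
    events: list[tuple[float, int, int, int, float]] = []
    for ev in model.events:
        t = v[ev.time_param]
        if ev.kind == "merge":
            events.append((t, 1, idx[ev.source_pop], idx[ev.dest_pop], 0.0))
        else:
            events.append((t, 0, idx[ev.source_pop], -1,
                           v[ev.new_size_param]))
    for b in model.bottlenecks:
        t = v[b.founding_time_param]
        db = v[b.duration_param]
        nb = v[b.bottleneck_size_param]
        i = idx[b.population]
        if db >= t:
            init[i] = nb  # bottleneck spans the whole post-founding period
        else:
            events.append((t - db, 0, i, -1, nb))
    events.sort(key=lambda e: (e[0], e[1]))  # size changes before merges
    arr = lambda j, dt: np.array([e[j] for e in events], dtype=dt)
    return CompiledDemography(
        pop_names=tuple(p.name for p in model.populations),
        sample_copies=np.array(
            [2 * p.n_diploid_samples for p in model.populations],
            dtype=np.int64),
        init_sizes=init.astype(np.float64),
        event_times=arr(0, np.float64),
        event_kinds=arr(1, np.int64),
        event_pop_a=arr(2, np.int64),
        event_pop_b=arr(3, np.int64),
        event_sizes=arr(4, np.float64),
    )


# ---------------------------------------------------------------------------
# YAML round-trip
# ---------------------------------------------------------------------------

def scenarios_to_yaml(models: list[ScenarioModel], path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(
            {"scenarios": [m.to_dict() for m in models]},
            fh, sort_keys=False,
        )


def scenarios_from_yaml(path) -> list[ScenarioModel]:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    return [ScenarioModel.from_dict(d) for d in doc["scenarios"]]
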