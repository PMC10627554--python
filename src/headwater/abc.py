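"""Approximate Bayesian computation: scenario choice, parameter estimation
and validation over simulated reference tables.

The workflow mirrors the standard rejection + regression ABC pipeline for
SNP data: simulate many datasets per scenario from the priors, summarize
each with the fixed summary vector, standardize all summaries jointly,
retain the 1% of simulations closest (Euclidean) to the observed vector,
then

* scenario choice — direct posterior = scenario proportions among retained
  rows; regression posterior = multinomial (polychotomous) logistic
  regression of scenario identity on the standardized summaries, evaluated
  at the observed point, with delta-method 95% CIs;
* parameter estimation — local-linear regression adjustment of the retained
  draws (parameters logit-mapped to their prior bounds so every adjusted
  value stays inside the prior);
* validation — posterior error rate from reclassified pseudo-observed
  datasets, and relative median absolute error (RMAE) of the point
  estimates on datasets with known truth.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import coalsim, sumstats
from .demography import ParameterDraw, ScenarioModel, draw_parameters

logger = logging.getLogger(__name__)

__all__ = [
    "ReferenceTable",
    "ModelChoiceResult",
    "PosteriorEstimate",
    "build_reference_table",
    "pca_prior_check",
    "model_choice",
    "estimate_parameters",
    "posterior_error_rate",
    "rmae",
]


@dataclass
class ReferenceTable:
    """Rows of (scenario id, parameter draw, summary vector).

    ``frame`` holds one column ``scenario_id``, parameter columns prefixed
    ``param_`` (NaN where a scenario lacks that parameter) and the summary
    columns.  Standardization statistics are computed jointly over all rows.
    """

    frame: pd.DataFrame
    stat_names: list[str]
    n_loci: int
    pop_names: list[str]

    @property
    def n_rows(self) -> int:
        return len(self.frame)

    @property
    def scenario_ids(self) -> list[int]:
        return sorted(self.frame["scenario_id"].unique().tolist())

    @property
    def param_names(self) -> list[str]:
        return [c[6:] for c in self.frame.columns if c.startswith("param_")]

    def stats_matrix(self) -> np.ndarray:
        return self.frame[self.stat_names].to_numpy(dtype=float)

    def standardizer(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(mean, sd, keep-mask); constant columns are flagged not scaled."""
        X = self.stats_matrix()
        mean = X.mean(axis=0)
        sd = X.std(axis=0, ddof=0)
        keep = sd > 0
        if not keep.all():
            dropped = [n for n, k in zip(self.stat_names, keep) if not k]
            warnings.warn(
                f"constant summary columns dropped: {dropped}", stacklevel=2
            )
        return mean, sd, keep

    def standardized(self, observed: np.ndarray | None = None):
        mean, sd, keep = self.standardizer()
        X = (self.stats_matrix()[:, keep] - mean[keep]) / sd[keep]
        if observed is None:
            return X, None
        obs = (np.asarray(observed, float)[keep] - mean[keep]) / sd[keep]
        return X, obs

    # -- I/O ---------------------------------------------------------------

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# summary layout v{sumstats.LAYOUT_VERSION}; "
                     f"n_loci={self.n_loci}; "
                     f"pops={','.join(self.pop_names)}\n")
            self.frame.to_csv(fh, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "ReferenceTable":
        with open(path) as fh:
            header = fh.readline().strip().lstrip("# ")
            fields = dict(
                kv.split("=") for kv in header.split("; ") if "=" in kv
            )
            frame = pd.read_csv(fh, sep="\t")
        stat_names = [
            c for c in frame.columns
            if c != "scenario_id" and not c.startswith("param_")
        ]
        return cls(frame, stat_names, int(fields.get("n_loci", 0)),
                   fields.get("pops", "").split(","))


def build_reference_table(
    models: list[ScenarioModel],
    n_per_scenario: int,
    n_loci: int,
    seed: int,
    out=None,
) -> ReferenceTable:
    """Simulate ``n_per_scenario`` datasets per scenario and summarize each.

    Fully deterministic for a fixed seed.  When ``out`` is given, rows are
    also streamed to that TSV path in chunks.
    """
    if n_per_scenario < 1:
        raise ValueError("n_per_scenario must be >= 1")
    rng = np.random.default_rng(seed)
    pop_names = [p.name for p in models[0].populations]
    stat_names = sumstats.summary_names(pop_names)
    all_params = sorted({p for m in models for p in m.parameter_names})
    records: list[dict] = []
    for model in models:
        for _ in range(n_per_scenario):
            draw = draw_parameters(model, rng)
            matrix = coalsim.simulate_snp_dataset(model, draw, n_loci, rng)
            vec = sumstats.compute_summary_vector(matrix, pop_names)
            rec: dict = {"scenario_id": model.scenario_id}
            for name in all_params:
                rec[f"param_{name}"] = draw.values.get(name, np.nan)
            rec.update(vec.as_dict())
            records.append(rec)
    frame = pd.DataFrame.from_records(records)
    table = ReferenceTable(frame, stat_names, n_loci, pop_names)
    if out is not None:
        table.to_tsv(out)
    return table


# ---------------------------------------------------------------------------
# PCA pre-evaluation
# ---------------------------------------------------------------------------

@dataclass
class PcaCheckReport:
    observed_pc: np.ndarray
    explained_variance_ratio: np.ndarray
    scenario_inside: dict[int, bool]

    @property
    def all_inside(self) -> bool:
        return all(self.scenario_inside.values())


def pca_prior_check(table: ReferenceTable,
                    observed: np.ndarray) -> PcaCheckReport:
    """Project the observed summaries into the first two principal
    components of the standardized simulated summaries and report, per
    scenario, whether the observation falls inside the component-wise range
    of that scenario's simulated cloud."""
    from sklearn.decomposition import PCA

    if table.n_rows == 0:
        raise ValueError("empty reference table")
    X, obs = table.standardized(observed)
    pca = PCA(n_components=min(2, X.shape[1]))
    scores = pca.fit_transform(X)
    obs_pc = pca.transform(obs.reshape(1, -1))[0]
    inside: dict[int, bool] = {}
    sid = table.frame["scenario_id"].to_numpy()
    for s in table.scenario_ids:
        cloud = scores[sid == s]
        inside[int(s)] = bool(
            np.all(obs_pc >= cloud.min(axis=0))
            and np.all(obs_pc <= cloud.max(axis=0))
        )
    return PcaCheckReport(obs_pc, pca.explained_variance_ratio_, inside)


# ---------------------------------------------------------------------------
# scenario choice
# ---------------------------------------------------------------------------

@dataclass
class ModelChoiceResult:
    direct_posterior: dict[int, float]
    logistic_posterior: dict[int, float]
    logistic_ci: dict[int, tuple[float, float]]
    retained_indices: np.ndarray
    distance_threshold: float

    @property
    def best_scenario(self) -> int:
        return max(self.direct_posterior, key=self.direct_posterior.get)


def _retained(table: ReferenceTable, observed, retain_fraction: float):
    X, obs = table.standardized(observed)
    d = np.sqrt(((X - obs) ** 2).sum(axis=1))
    n_keep = math.ceil(retain_fraction * table.n_rows)
    order = np.argsort(d, kind="stable")  # distance ties broken by row index
    idx = order[:n_keep]
    return X, obs, d, idx


def model_choice(table: ReferenceTable, observed: np.ndarray,
                 retain_fraction: float = 0.01) -> ModelChoiceResult:
    """ABC scenario choice by rejection plus multinomial logistic regression.

    Retains ``ceil(retain_fraction * N)`` simulations closest to the
    observed summaries in standardized Euclidean distance.  The direct
    posterior is the retained scenario proportions; the regression posterior
    evaluates a multinomial logistic fit (scenario ~ standardized summaries
    over retained rows) at the observed point, with 95% CIs from the
    asymptotic covariance by the delta method, truncated to [0, 1].
    """
    if not (0 < retain_fraction <= 1):
        raise ValueError("retain_fraction must be in (0, 1]")
    if len(table.scenario_ids) < 2:
        raise ValueError("model choice needs >= 2 scenarios in the table")
    X, obs, d, idx = _retained(table, observed, retain_fraction)
    sid = table.frame["scenario_id"].to_numpy()
    ret_sid = sid[idx]
    scenarios = table.scenario_ids
    direct = {
        int(s): float((ret_sid == s).mean()) for s in scenarios
    }
    present = [s for s in scenarios if (ret_sid == s).any()]
    absent = [s for s in scenarios if s not in present]
    if absent:
        logger.warning(
            "scenarios absent from retained rows (probability 0): %s", absent
        )
    logistic: dict[int, float] = {int(s): 0.0 for s in scenarios}
    ci: dict[int, tuple[float, float]] = {
        int(s): (0.0, 0.0) for s in scenarios
    }
    if len(present) == 1:
        logistic[int(present[0])] = 1.0
        ci[int(present[0])] = (1.0, 1.0)
    else:
        probs, cis = _multinomial_logistic(X[idx], ret_sid, obs, present)
        for s, p, c in zip(present, probs, cis):
            logistic[int(s)] = float(p)
            ci[int(s)] = c
    return ModelChoiceResult(
        direct_posterior=direct,
        logistic_posterior=logistic,
        logistic_ci=ci,
        retained_indices=idx,
        distance_threshold=float(d[idx].max()),
    )


def _multinomial_logistic(Xr, yr, obs, present):
    """Fit scenario ~ summaries (MNLogit) on retained rows; return predicted
    probabilities at the observed point and delta-method 95% CIs."""
    import statsmodels.api as sm

    code = {s: i for i, s in enumerate(present)}
    y = np.array([code[s] for s in yr])
    exog = sm.add_constant(Xr, has_constant="add")
    x_obs = np.concatenate([[1.0], obs])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.MNLogit(y, exog)
        try:
            res = model.fit(method="lbfgs", maxiter=1000, disp=False)
            params = np.asarray(res.params)
            cov = np.asarray(res.cov_params())
        except Exception:  # singular Hessian under separation
            res = model.fit(method="bfgs", maxiter=200, disp=False,
                            full_output=True)
            params = np.asarray(res.params)
            H = model.hessian(params.ravel(order="F"))
            cov = np.linalg.pinv(-H)

    def predict(theta_flat):
        th = theta_flat.reshape(params.shape, order="F")
        eta = np.concatenate([[0.0], x_obs @ th])
        eta -= eta.max()
        e = np.exp(eta)
        return e / e.sum()

    theta = params.ravel(order="F")
    probs = predict(theta)
    # numerical delta method: gradient of each class probability
    eps = 1e-5
    grad = np.zeros((len(present), theta.size))
    for j in range(theta.size):
        tp = theta.copy()
        tp[j] += eps
        tm = theta.copy()
        tm[j] -= eps
        grad[:, j] = (predict(tp) - predict(tm)) / (2 * eps)
    cis = []
    for i in range(len(present)):
        var = float(grad[i] @ cov @ grad[i])
        half = 1.959963984540054 * math.sqrt(max(var, 0.0))
        cis.append((max(0.0, probs[i] - half), min(1.0, probs[i] + half)))
    return probs, cis


# ---------------------------------------------------------------------------
# parameter estimation (rejection + local-linear adjustment)
# ---------------------------------------------------------------------------

@dataclass
class PosteriorEstimate:
    parameter_names: list[str]
    posterior_sample: pd.DataFrame      # adjusted draws, one column per param
    median: dict[str, float]
    ci95: dict[str, tuple[float, float]]
    adjusted: bool = True
    flags: list[str] = field(default_factory=list)


def _logit_to_bounds(x, lo, hi):
    eps = 1e-9 * (hi - lo)
    xc = np.clip(x, lo + eps, hi - eps)
    return np.log((xc - lo) / (hi - xc))


def _inv_logit_from_bounds(z, lo, hi):
    return lo + (hi - lo) / (1.0 + np.exp(-z))


def estimate_parameters(table: ReferenceTable, observed: np.ndarray,
                        model: ScenarioModel,
                        retain_fraction: float = 0.01) -> PosteriorEstimate:
    """Local-linear regression-adjusted ABC posterior for one scenario.

    The table must contain only (or be filtered to) the target scenario's
    rows.  Each parameter is logit-mapped to its prior bounds, regressed on
    the standardized summaries over the retained rows (Epanechnikov
    distance weights), residual-adjusted to the observed point, and mapped
    back — so every adjusted draw respects the prior support.
    """
    sub = table.frame[table.frame["scenario_id"] == model.scenario_id]
    if len(sub) == 0:
        raise ValueError(f"no rows for scenario {model.scenario_id}")
    sub_table = ReferenceTable(sub.reset_index(drop=True), table.stat_names,
                               table.n_loci, table.pop_names)
    X, obs, d, idx = _retained(sub_table, observed, retain_fraction)
    if idx.size < 50:
        raise ValueError(
            f"only {idx.size} retained rows; need >= 50 for the regression"
        )
    dmax = d[idx].max()
    w = (1.0 - (d[idx] / dmax) ** 2) if dmax > 0 else np.ones(idx.size)
    w = np.maximum(w, 1e-12)
    Xr = X[idx]
    design = np.column_stack([np.ones(idx.size), Xr - obs])
    sw = np.sqrt(w)
    flags: list[str] = []
    names = model.parameter_names
    adj: dict[str, np.ndarray] = {}
    for name in names:
        prior = model.prior(name)
        vals = sub_table.frame[f"param_{name}"].to_numpy(float)[idx]
        z = _logit_to_bounds(vals, prior.lower, prior.upper)
        coef, *_ = np.linalg.lstsq(design * sw[:, None], z * sw, rcond=None)
        if not np.all(np.isfinite(coef)):
            flags.append(f"{name}: singular design, rejection posterior used")
            z_adj = z
        else:
            # Beaumont adjustment: alpha + residuals = z - (S - s_obs) beta
            z_adj = z - (design[:, 1:] @ coef[1:])
        adj[name] = _inv_logit_from_bounds(z_adj, prior.lower, prior.upper)
    post = pd.DataFrame(adj)
    return PosteriorEstimate(
        parameter_names=names,
        posterior_sample=post,
        median={n: float(post[n].median()) for n in names},
        ci95={
            n: (float(post[n].quantile(0.025)),
                float(post[n].quantile(0.975)))
            for n in names
        },
        flags=flags,
    )


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------

def _simulate_summary(model: ScenarioModel, draw: ParameterDraw,
                      n_loci: int, pop_names: list[str], rng) -> np.ndarray:
    matrix = coalsim.simulate_snp_dataset(model, draw, n_loci, rng)
    return sumstats.compute_summary_vector(matrix, pop_names).values


def posterior_error_rate(table: ReferenceTable,
                         models: list[ScenarioModel],
                         selected_scenario: int,
                         observed: np.ndarray,
                         n_pseudo: int,
                         seed: int,
                         retain_fraction: float = 0.01) -> float:
    """Misclassification rate of ABC scenario choice near the observed data.

    ``n_pseudo`` pseudo-observed datasets are simulated under the selected
    scenario with parameters drawn from its regression-adjusted posterior
    (given ``observed``), plus ``n_pseudo`` from each competing scenario's
    prior; each is reclassified with :func:`model_choice` and the fraction
    assigned a scenario other than its generator is returned.
    """
    if n_pseudo < 1:
        raise ValueError("n_pseudo must be >= 1")
    rng = np.random.default_rng(seed)
    by_id = {m.scenario_id: m for m in models}
    sel = by_id[selected_scenario]
    post = estimate_parameters(table, observed, sel,
                               retain_fraction=retain_fraction)
    sample = post.posterior_sample
    n_wrong = 0
    n_total = 0
    for sid, m in by_id.items():
        for _ in range(n_pseudo):
            if sid == selected_scenario:
                row = sample.iloc[int(rng.integers(len(sample)))]
                draw = ParameterDraw(sid, {k: float(v)
                                           for k, v in row.items()})
            else:
                draw = draw_parameters(m, rng)
            s = _simulate_summary(m, draw, table.n_loci, table.pop_names,
                                  rng)
            result = model_choice(table, s, retain_fraction)
            n_wrong += int(result.best_scenario != sid)
            n_total += 1
    return n_wrong / n_total


def rmae(models: list[ScenarioModel], scenario: int, n_pseudo: int,
         table: ReferenceTable, seed: int,
         retain_fraction: float = 0.01) -> dict[str, float]:
    """Relative median absolute error of the ABC point estimates.

    For each of ``n_pseudo`` pseudo-observed datasets simulated under the
    target scenario with known parameters, the posterior median is computed
    and RMAE(param) = median over datasets of |estimate - truth| / truth.
    """
    if n_pseudo < 10:
        raise ValueError("n_pseudo must be >= 10")
    rng = np.random.default_rng(seed)
    model = next(m for m in models if m.scenario_id == scenario)
    errors: dict[str, list[float]] = {n: [] for n in model.parameter_names}
    for _ in range(n_pseudo):
        truth = draw_parameters(model, rng)
        s = _simulate_summary(model, truth, table.n_loci, table.pop_names,
                              rng)
        est = estimate_parameters(table, s, model,
                                  retain_fraction=retain_fraction)
        for name in model.parameter_names:
            tv = truth.values[name]
            if tv == 0:
                logger.info("rmae: truth 0 for %s, dataset excluded", name)
                continue
            errors[name].append(abs(est.median[name] - tv) / tv)
    return {n: float(np.median(v)) for n, v in errors.items() if v}
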