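"""Seeded synthetic SNP datasets with recorded ground truth.

Stands in for a real GBS SNP deposit: every dataset is simulated under a
named demographic scenario with a recorded parameter draw and seed, written
as uncompressed VCF + popmap + a JSON metadata sidecar, and is
bit-reproducible from that metadata.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

from . import abc as abc_mod
from . import coalsim
from .demography import (
    BASIN_SAMPLE_SIZES,
    ParameterDraw,
    ScenarioModel,
    all_capture_scenarios,
    build_capture_scenario,
    draw_parameters,
)
from .genotypes import GenotypeSnpMatrix

__all__ = ["TruthBundle", "generate_truth_dataset", "make_fixture_suite"]


@dataclass
class TruthBundle:
    """A synthetic dataset plus everything needed to regenerate it."""

    matrix: GenotypeSnpMatrix
    scenario_id: int
    draw: ParameterDraw
    seed: int
    n_loci: int

    def write(self, out_dir, prefix: str = "truth") -> dict[str, Path]:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        vcf = out / f"{prefix}.vcf"
        popmap = out / f"{prefix}.popmap"
        meta = out / f"{prefix}.json"
        self.matrix.write_vcf(vcf)
        self.matrix.write_popmap(popmap)
        with open(meta, "w") as fh:
            json.dump(
                {
                    "scenario_id": self.scenario_id,
                    "parameters": self.draw.values,
                    "seed": self.seed,
                    "n_loci": self.n_loci,
                    "sample_sizes": {
                        p: self.matrix.populations.count(p)
                        for p in self.matrix.population_names
                    },
                    "vcf_sha256": _sha256(vcf),
                },
                fh, indent=1, sort_keys=True,
            )
        return {"vcf": vcf, "popmap": popmap, "metadata": meta}


def _sha256(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def generate_truth_dataset(
    scenario_id: int,
    params: ParameterDraw | None = None,
    n_loci: int = 2000,
    sample_sizes: dict[str, int] | None = None,
    seed: int = 0,
    model: ScenarioModel | None = None,
) -> TruthBundle:
    """Simulate one SNP dataset under a scenario and record its truth.

    With ``params=None`` the parameters are drawn from the scenario's
    priors (seeded).  Sample sizes default to the 6/5/4/9/9 study design.
    No genotype is missing.
    """
    if model is None:
        model = build_capture_scenario(scenario_id,
                                       sample_sizes=sample_sizes)
    draw = params if params is not None else draw_parameters(model, seed)
    matrix = coalsim.simulate_snp_dataset(model, draw, n_loci, seed=seed + 1)
    return TruthBundle(matrix, scenario_id, draw, seed, n_loci)


def make_fixture_suite(out_dir, seed: int = 0) -> dict[str, Path]:
    """Write the small canned fixtures the test-suite and examples use:
    a two-population toy VCF, a five-basin scenario-3 dataset, a six-scenario
    mini reference table, and a checksum manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    toy_model = build_capture_scenario(3)
    toy = generate_truth_dataset(3, n_loci=50, seed=seed, model=toy_model)
    two_pop = toy.matrix.subset_populations(["Paraguacu", "Contas"])
    paths["toy_vcf"] = out / "toy_two_pop.vcf"
    paths["toy_popmap"] = out / "toy_two_pop.popmap"
    two_pop.write_vcf(paths["toy_vcf"])
    two_pop.write_popmap(paths["toy_popmap"])

    full = generate_truth_dataset(3, n_loci=500, seed=seed + 10)
    written = full.write(out, prefix="scenario3_500loci")
    paths.update({f"scenario3_{k}": v for k, v in written.items()})

    table = abc_mod.build_reference_table(
        all_capture_scenarios(), n_per_scenario=60, n_loci=200,
        seed=seed + 20,
    )
    paths["mini_table"] = out / "mini_reference_table.tsv"
    table.to_tsv(paths["mini_table"])

    manifest = {k: _sha256(v) for k, v in sorted(paths.items())}
    paths["manifest"] = out / "checksums.json"
    with open(paths["manifest"], "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return paths
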