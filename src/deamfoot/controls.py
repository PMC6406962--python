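"""Control experiments for the weight-matrix footprint method.

Four reusable controls quantify the method's false-positive behavior:

1. negative set — a mutation table where no motif enrichment is expected
   (e.g. mitochondrial mutations, or a synthetic motif-free table);
2. shuffled matrices — matrices rebuilt from per-sequence shuffled contexts
   (center fixed), which preserve composition but destroy the motif;
3. random matrices — matrices built from composition-matched random genomic
   sites ("pseudo-mutable motifs");
4. positive set — mutations planted in a known motif (the immunoglobulin
   somatic-hypermutation analog), which the matching matrix must detect.

Each run reports per-(matrix x group) outcomes and the aggregate fraction of
dual-test significant results — the false-positive fraction on null inputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .context_io import Genome, MutationRecord, sample_matched_sites, shuffle_context
from .footprint import FootprintResult, derive_seed, footprint_scan, results_table
from .motif_matrix import ContextWindow, WeightMatrix, build_weight_matrix, count_contexts

UNRELIABLE_FP_THRESHOLD = 0.25  # matrices above this FP fraction are flagged


@dataclass
class ControlReport:
    """Outcome table and aggregate false-positive fraction of a control run."""

    control_kind: str  # shuffle | random_matrix | negative_set | positive_set
    outcomes: pd.DataFrame
    seed: int
    replicates: int
    unreliable_matrices: list[str] = field(default_factory=list)

    @property
    def n_outcomes(self) -> int:
        return int(self.outcomes["significant"].notna().sum())

    @property
    def fp_fraction(self) -> float:
        """Significant outcomes / total decidable outcomes."""
        sig = self.outcomes["significant"].dropna()
        if len(sig) == 0:
            return float("nan")
        return float(sig.astype(bool).mean())

    def per_matrix_fp(self) -> pd.Series:
        """FP fraction per matrix template (aggregated over replicates/groups)."""
        df = self.outcomes.dropna(subset=["significant"])
        return df.groupby("template")["significant"].mean()

    def fp_table(self) -> pd.DataFrame:
        """Template x group table of significant fractions (heatmap-ready)."""
        df = self.outcomes.dropna(subset=["significant"]).copy()
        df["group"] = df["tissue"] + " " + df["subclass"]
        return df.pivot_table(
            index="template", columns="group", values="significant", aggfunc="mean"
        )

    def to_json(self, path) -> None:
        import json

        payload = {
            "control_kind": self.control_kind,
            "seed": self.seed,
            "replicates": self.replicates,
            "n_outcomes": self.n_outcomes,
            "fp_fraction": self.fp_fraction,
            "unreliable_matrices": self.unreliable_matrices,
            "outcomes": self.outcomes.to_dict(orient="records"),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, default=float)


def _outcome_rows(
    results: Sequence[FootprintResult], replicate: int, template_of: Mapping[str, str]
) -> pd.DataFrame:
    df = results_table(results)
    df.insert(0, "replicate", replicate)
    df.insert(1, "template", df["matrix"].map(template_of))
    return df


def _finalize(
    kind: str, frames: list[pd.DataFrame], seed: int, replicates: int
) -> ControlReport:
    outcomes = pd.concat(frames, ignore_index=True)
    report = ControlReport(
        control_kind=kind, outcomes=outcomes, seed=seed, replicates=replicates
    )
    per_matrix = report.per_matrix_fp()
    report.unreliable_matrices = sorted(
        per_matrix.index[per_matrix > UNRELIABLE_FP_THRESHOLD]
    )
    return report


def run_shuffle_control(
    context_sets: Mapping[str, Sequence[ContextWindow]],
    records: Sequence[MutationRecord],
    genome: Genome,
    replicates: int = 4,
    seed: int = 0,
    mc_iters: int = 1000,
    n_min: int = 50,
    **scan_kwargs,
) -> ControlReport:
    """Footprint scan against matrices rebuilt from per-sequence shuffled contexts.

    Each replicate shuffles the 10 flanking bases of every training window
    (center fixed, per-sequence composition preserved), rebuilds the weight
    matrices, and runs the scan. On null mutation sets the fraction of
    dual-test significant outcomes estimates the false-discovery behavior.
    """
    frames = []
    for r in range(replicates):
        matrices: dict[str, WeightMatrix] = {}
        template_of: dict[str, str] = {}
        for name, windows in context_sets.items():
            rng = np.random.default_rng(derive_seed(seed, "shuffle", name, str(r)))
            shuffled = [shuffle_context(w, rng) for w in windows]
            mid = f"{name}_shuf{r}"
            matrices[mid] = build_weight_matrix(count_contexts(shuffled), label=mid)
            template_of[mid] = name
        results = footprint_scan(
            matrices, records, genome,
            mc_iters=mc_iters, seed=derive_seed(seed, "scan", str(r)),
            n_min=n_min, **scan_kwargs,
        )
        frames.append(_outcome_rows(results, r, template_of))
    return _finalize("shuffle", frames, seed, replicates)


def run_random_matrix_control(
    genome: Genome,
    template_sets: Mapping[str, Sequence[ContextWindow]],
    records: Sequence[MutationRecord],
    replicates: int = 4,
    seed: int = 0,
    mc_iters: int = 1000,
    n_min: int = 50,
    sampling_genome: Genome | None = None,
    tol: float = 0.01,
    **scan_kwargs,
) -> ControlReport:
    """Footprint scan against matrices built from composition-matched random sites.

    For each template context set and replicate, random C/G-centered windows
    matching the template's base composition are sampled from the genome
    ("pseudo-mutable motifs") and a matrix is built from them. Matrices whose
    aggregate false-positive fraction exceeds 0.25 are flagged unreliable.
    """
    sampling_genome = sampling_genome if sampling_genome is not None else genome
    frames = []
    for r in range(replicates):
        matrices: dict[str, WeightMatrix] = {}
        template_of: dict[str, str] = {}
        for name, windows in template_sets.items():
            rng = np.random.default_rng(derive_seed(seed, "sample", name, str(r)))
            sampled = sample_matched_sites(sampling_genome, list(windows), rng, tol=tol)
            mid = f"{name}_rand{r}"
            matrices[mid] = build_weight_matrix(count_contexts(sampled), label=mid)
            template_of[mid] = name
        results = footprint_scan(
            matrices, records, genome,
            mc_iters=mc_iters, seed=derive_seed(seed, "scan", str(r)),
            n_min=n_min, **scan_kwargs,
        )
        frames.append(_outcome_rows(results, r, template_of))
    return _finalize("random_matrix", frames, seed, replicates)


def run_negative_control(
    matrices: Mapping[str, WeightMatrix],
    negative_records: Sequence[MutationRecord],
    genome: Genome,
    seed: int = 0,
    mc_iters: int = 1000,
    n_min: int = 50,
    **scan_kwargs,
) -> ControlReport:
    """Plain scan on a mutation set where no motif enrichment is expected.

    The outcome table's ``single_test_hit`` column marks results where exactly
    one of the two tests fired; these are not counted as significant (the
    dual gate requires both).
    """
    results = footprint_scan(
        matrices, negative_records, genome,
        mc_iters=mc_iters, seed=seed, n_min=n_min, **scan_kwargs,
    )
    df = _outcome_rows(results, 0, {m: m for m in matrices})
    t_crit = results[0].t_critical
    mc_alpha = results[0].mc_alpha
    t_hit = df["t"] >= t_crit
    mc_hit = df["mc_p"] < mc_alpha
    df["single_test_hit"] = (t_hit ^ mc_hit) & df["significant"].notna()
    report = _finalize("negative_set", [df], seed, 1)
    return report


def run_positive_control(
    matrices: Mapping[str, WeightMatrix],
    positive_records: Sequence[MutationRecord],
    genome: Genome,
    seed: int = 0,
    mc_iters: int = 1000,
    n_min: int = 50,
    **scan_kwargs,
) -> ControlReport:
    """Plain scan on a known-signal set (the immunoglobulin-gene analog).

    Expectation: the matrix matching the planted motif is dual-test
    significant; non-matching matrices are not.
    """
    results = footprint_scan(
        matrices, positive_records, genome,
        mc_iters=mc_iters, seed=seed, n_min=n_min, **scan_kwargs,
    )
    df = _outcome_rows(results, 0, {m: m for m in matrices})
    return _finalize("positive_set", [df], seed, 1)
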