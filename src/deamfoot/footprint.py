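"""Mutational-footprint statistic: mean-weight ratio with dual significance.

For each somatic C:G mutation the percent matching score ("weight") of its
context window is compared with the weights of all other C/G sites in the
121-bp DNA neighborhood of the mutation. The ratio of mean weights
(mutated / non-mutated) exceeds 1 when mutations fall preferentially into a
deaminase's mutable motif. A correlation is claimed only when both a Welch
2-tailed t-test and a 1-tailed Monte Carlo test are significant, with the
t gate Bonferroni-corrected over the scan's family of tests.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view
from scipy import stats

from .context_io import (
    CG_CLASSES,
    Genome,
    MutationRecord,
    eligible_background_sites,
    extract_neighborhood,
)
from .motif_matrix import (
    WINDOW_LEN,
    WeightMatrix,
    encode_bases,
    percent_from_scores,
)

DEFAULT_MC_ITERS = 1000
DEFAULT_N_MIN = 50


def conservative_t_critical(alpha: float = 0.05, n_tests: int = 1) -> float:
    """Large-sample 2-tailed t critical value after Bonferroni correction.

    Uses the normal quantile (the conservative large-sample limit); e.g.
    alpha=0.05 over 24 tests gives 3.1 to one decimal.
    """
    return float(stats.norm.isf(alpha / n_tests / 2.0))


@dataclass
class FootprintResult:
    """One (tissue x substitution class x matrix) footprint test."""

    tissue: str
    subclass: str
    matrix_id: str
    n_mutations: int
    mean_weight_mutated: float
    mean_weight_background: float
    ratio: float  # nan when degenerate (background mean 0)
    t_statistic: float
    t_p: float  # 2-tailed
    mc_p: float  # 1-tailed
    significant: bool | None  # None when the group is below n_min
    t_critical: float
    mc_alpha: float
    fraction: float | None = None
    degenerate: bool = False
    n_background_sites: int = 0


@dataclass
class EncodedRecord:
    """Pre-encoded scoring data for one mutation record.

    ``mut_codes``: base codes (length 11) of the strand-normalized mutated
    window; ``bg_codes``: (m, 11) codes of the strand-normalized windows at
    the m eligible non-mutated C/G sites of the neighborhood.
    """

    record: MutationRecord
    mut_codes: np.ndarray
    bg_codes: np.ndarray


def encode_records(
    genome: Genome, records: Sequence[MutationRecord]
) -> tuple[list[EncodedRecord], pd.DataFrame]:
    """Extract and encode windows/neighborhoods once, for reuse across matrices.

    Records that cannot be scored (non-C:G ref, edge, N in context) are
    skipped and returned in a log frame with reasons.
    """
    encoded: list[EncodedRecord] = []
    skipped: list[dict] = []
    for rec in records:
        if rec.ref not in "CG":
            skipped.append({"chrom": rec.chrom, "pos": rec.pos, "reason": "non_cg_ref"})
            continue
        try:
            nb = extract_neighborhood(genome, rec)
        except ValueError as exc:
            skipped.append({"chrom": rec.chrom, "pos": rec.pos, "reason": str(exc)})
            continue
        if "N" in nb.seq:
            skipped.append({"chrom": rec.chrom, "pos": rec.pos, "reason": "ambiguous"})
            continue
        nb_codes = encode_bases(nb.seq)
        mut_codes = _normalized_site_codes(nb_codes, np.array([60]))[0]
        offsets = eligible_background_sites(nb)
        bg_codes = _normalized_site_codes(nb_codes, offsets)
        encoded.append(EncodedRecord(record=rec, mut_codes=mut_codes, bg_codes=bg_codes))
    return encoded, pd.DataFrame(skipped, columns=["chrom", "pos", "reason"])


def _normalized_site_codes(nb_codes: np.ndarray, offsets: np.ndarray) -> np.ndarray:
    """(m, 11) strand-normalized window codes at C/G offsets of a neighborhood."""
    if len(offsets) == 0:
        return np.empty((0, WINDOW_LEN), dtype=np.uint8)
    views = sliding_window_view(nb_codes, WINDOW_LEN)  # (121-10, 11)
    wins = views[offsets - 5].copy()
    is_g = nb_codes[offsets] == 2  # G-centered: reverse complement
    if np.any(is_g):
        wins[is_g] = (3 - wins[is_g])[:, ::-1]
    return wins


def _percent_weights(wm: WeightMatrix, codes: np.ndarray) -> np.ndarray:
    cols = np.asarray(wm.scoring_columns)
    scores = wm.W[codes[..., cols], cols].sum(axis=-1)
    return np.asarray(percent_from_scores(wm, scores))


def site_weights(
    wm: WeightMatrix,
    records: Sequence[MutationRecord],
    genome: Genome,
) -> list[float]:
    """Percent score of each mutation's own context window (input order kept)."""
    encoded, _ = encode_records(genome, records)
    return [float(_percent_weights(wm, er.mut_codes)) for er in encoded]


def background_weights(
    wm: WeightMatrix,
    records: Sequence[MutationRecord],
    genome: Genome,
) -> list[float]:
    """Percent scores at every eligible neighborhood site of every record, pooled."""
    encoded, _ = encode_records(genome, records)
    out: list[float] = []
    for er in encoded:
        out.extend(_percent_weights(wm, er.bg_codes).tolist())
    return out


def footprint(
    wm: WeightMatrix,
    records: Sequence[MutationRecord] | None,
    genome: Genome | None,
    mc_iters: int = DEFAULT_MC_ITERS,
    seed: int = 0,
    n_min: int = DEFAULT_N_MIN,
    mc_alpha: float = 0.05,
    t_critical: float | None = None,
    family_size: int = 1,
    tissue: str = "",
    subclass: str = "",
    matrix_id: str | None = None,
    encoded: Sequence[EncodedRecord] | None = None,
) -> FootprintResult:
    """Run the dual-test footprint analysis for one group of mutations.

    The Monte Carlo test draws, in each of ``mc_iters`` iterations, one
    uniformly random eligible site from each record's own neighborhood and
    compares the mean of the draws with the observed mean mutated weight;
    mc_p = (1 + #{iteration means >= observed}) / (mc_iters + 1).
    """
    if encoded is None:
        if records is None or genome is None:
            raise ValueError("provide either encoded records or (records, genome)")
        encoded, _ = encode_records(genome, records)
    if not encoded:
        raise ValueError("no scoreable records")
    if t_critical is None:
        t_critical = conservative_t_critical(0.05, family_size)
    rng = np.random.default_rng(seed)
    # canonical record order: MC draws depend only on content, not input order
    encoded = sorted(
        encoded,
        key=lambda er: (er.record.chrom, er.record.pos, er.record.alt, er.record.sample_id),
    )

    mut_codes = np.stack([er.mut_codes for er in encoded])
    mut_w = _percent_weights(wm, mut_codes)
    bg_lists = [_percent_weights(wm, er.bg_codes) for er in encoded if len(er.bg_codes)]
    n = len(encoded)
    obs_mean = float(mut_w.mean())

    if not bg_lists:
        return FootprintResult(
            tissue=tissue, subclass=subclass,
            matrix_id=matrix_id if matrix_id is not None else wm.label,
            n_mutations=n, mean_weight_mutated=obs_mean,
            mean_weight_background=np.nan, ratio=np.nan,
            t_statistic=np.nan, t_p=np.nan, mc_p=np.nan,
            significant=None, t_critical=t_critical, mc_alpha=mc_alpha,
            degenerate=True,
        )

    bg_all = np.concatenate(bg_lists)
    bg_mean = float(bg_all.mean())
    degenerate = bg_mean == 0.0
    ratio = obs_mean / bg_mean if not degenerate else np.nan

    t_stat, t_p = stats.ttest_ind(mut_w, bg_all, equal_var=False)

    # Monte Carlo: one draw per record per iteration from its own neighborhood
    sums = np.zeros(mc_iters)
    for w in bg_lists:
        sums += w[rng.integers(0, len(w), size=mc_iters)]
    mc_means = sums / len(bg_lists)
    mc_p = (1.0 + float(np.sum(mc_means >= obs_mean))) / (mc_iters + 1.0)

    if n < n_min:
        significant: bool | None = None
    else:
        significant = bool(
            not degenerate and t_stat >= t_critical and mc_p < mc_alpha
        )
    return FootprintResult(
        tissue=tissue,
        subclass=subclass,
        matrix_id=matrix_id if matrix_id is not None else wm.label,
        n_mutations=n,
        mean_weight_mutated=obs_mean,
        mean_weight_background=bg_mean,
        ratio=float(ratio),
        t_statistic=float(t_stat),
        t_p=float(t_p),
        mc_p=float(mc_p),
        significant=significant,
        t_critical=float(t_critical),
        mc_alpha=mc_alpha,
        degenerate=degenerate,
        n_background_sites=int(bg_all.size),
    )


def derive_seed(master_seed: int, *labels: str) -> int:
    """Stable per-(group, matrix) seed below 2**31, independent of record order."""
    digest = hashlib.sha256(
        ("|".join([str(master_seed), *labels])).encode()
    ).hexdigest()
    return int(digest[:8], 16) % (2**31)


def footprint_scan(
    matrices: Mapping[str, WeightMatrix],
    records: Sequence[MutationRecord],
    genome: Genome,
    mc_iters: int = DEFAULT_MC_ITERS,
    seed: int = 0,
    n_min: int = DEFAULT_N_MIN,
    mc_alpha: float = 0.05,
    family_alpha: float = 0.05,
    family_size: int | None = None,
    classes: Sequence[str] = CG_CLASSES,
) -> list[FootprintResult]:
    """One footprint test per (tissue x substitution class x matrix).

    Only strand-collapsed C:G classes are scoreable by the C-centered
    deaminase matrices. The Bonferroni family defaults to (number of groups)
    x (number of matrices); each test's seed is derived from the master seed
    and the group/matrix labels so results are record-order independent.
    """
    groups: dict[tuple[str, str], list[MutationRecord]] = {}
    for rec in records:
        if rec.ref not in "CG" or rec.subclass not in classes:
            continue
        groups.setdefault((rec.tissue, rec.subclass), []).append(rec)
    if not groups or not matrices:
        raise ValueError("need at least one group and one matrix")
    if family_size is None:
        family_size = len(groups) * len(matrices)
    t_crit = conservative_t_critical(family_alpha, family_size)
    results: list[FootprintResult] = []
    for (tissue, subclass), recs in sorted(groups.items()):
        encoded, _ = encode_records(genome, recs)
        for mid, wm in matrices.items():
            results.append(
                footprint(
                    wm,
                    None,
                    None,
                    mc_iters=mc_iters,
                    seed=derive_seed(seed, tissue, subclass, mid),
                    n_min=n_min,
                    mc_alpha=mc_alpha,
                    t_critical=t_crit,
                    tissue=tissue,
                    subclass=subclass,
                    matrix_id=mid,
                    encoded=encoded,
                )
            )
    return results


def results_table(results: Iterable[FootprintResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        rows.append(
            {
                "tissue": r.tissue,
                "subclass": r.subclass,
                "matrix": r.matrix_id,
                "n": r.n_mutations,
                "mean_mutated": r.mean_weight_mutated,
                "mean_background": r.mean_weight_background,
                "ratio": r.ratio,
                "t": r.t_statistic,
                "t_p": r.t_p,
                "mc_p": r.mc_p,
                "significant": r.significant,
                "fraction": r.fraction,
            }
        )
    return pd.DataFrame(rows)


def write_results_tsv(results: Iterable[FootprintResult], path) -> None:
    """Summary-table layout: Ratio / t / MC / Fraction rows per group."""
    df = results_table(results)
    matrices = sorted(df["matrix"].unique())
    lines = ["\t".join(["group", "n", "test"] + matrices)]
    for (tissue, subclass), sub in df.groupby(["tissue", "subclass"]):
        sub = sub.set_index("matrix")
        n = int(sub["n"].iloc[0])
        group = f"{tissue} {subclass}"

        def _row(label, fmt):
            vals = []
            for m in matrices:
                if m not in sub.index:
                    vals.append("")
                    continue
                vals.append(fmt(sub.loc[m]))
            return "\t".join([group, str(n), label] + vals)

        lines.append(_row("Ratio", lambda r: f"{r['ratio']:.3f}"))
        lines.append(
            _row(
                "t-test",
                lambda r: f"{r['t']:.1f} *" if r["significant"] else "NSE",
            )
        )
        lines.append(
            _row(
                "MC test",
                lambda r: "<0.001" if r["mc_p"] < 0.001 else f"{r['mc_p']:.3f}",
            )
        )
        lines.append(
            _row(
                "Fraction",
                lambda r: "" if pd.isna(r["fraction"]) or r["fraction"] is None
                else f"{r['fraction']:.3f}",
            )
        )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# UPGMA clustering of ratio profiles


def upgma_newick(labels: Sequence[str], dist: np.ndarray) -> str:
    """Average-linkage (UPGMA) clustering, returned as a Newick string.

    Ties are broken by merging the pair whose sorted leaf-label tuples are
    lexicographically smallest, making the output deterministic. Branch
    lengths are differences of merge heights (height = distance / 2).
    """
    dist = np.asarray(dist, dtype=float)
    n = len(labels)
    if dist.shape != (n, n):
        raise ValueError("distance matrix shape mismatch")
    if np.any(np.isnan(dist)):
        raise ValueError("missing cells in distance matrix")
    # cluster state: newick fragment, leaf-label key, size, height
    clusters: dict[int, tuple[str, tuple[str, ...], int, float]] = {
        i: (str(labels[i]), (str(labels[i]),), 1, 0.0) for i in range(n)
    }
    d = {frozenset((i, j)): float(dist[i, j]) for i in range(n) for j in range(i + 1, n)}
    next_id = n
    while len(clusters) > 1:
        best = None
        for pair, dv in d.items():
            i, j = sorted(pair)
            key = tuple(sorted((clusters[i][1], clusters[j][1])))
            cand = (dv, key)
            if best is None or cand < best[0]:
                best = (cand, i, j)
        _, i, j = best
        dij = d[frozenset((i, j))]
        h = dij / 2.0
        ni, nj = clusters[i], clusters[j]
        first, second = (ni, nj) if ni[1] <= nj[1] else (nj, ni)  # canonical child order
        newick = f"({first[0]}:{h - first[3]:.12g},{second[0]}:{h - second[3]:.12g})"
        merged_key = tuple(sorted(ni[1] + nj[1]))
        size = ni[2] + nj[2]
        for k in list(clusters):
            if k in (i, j):
                continue
            dk = (
                ni[2] * d[frozenset((i, k))] + nj[2] * d[frozenset((j, k))]
            ) / size
            d[frozenset((next_id, k))] = dk
        for pair in [p for p in d if i in p or j in p]:
            del d[pair]
        del clusters[i], clusters[j]
        clusters[next_id] = (newick, merged_key, size, h)
        next_id += 1
    (newick, _, _, _), = clusters.values()
    return newick + ";"


def upgma_cluster(ratio_table: pd.DataFrame) -> tuple[str, str]:
    """UPGMA dendrograms (rows, columns) of a complete tissue x matrix ratio table.

    Distances are Euclidean on ratio vectors. Raises on missing cells.
    """
    if ratio_table.isna().any().any():
        raise ValueError("missing cells in ratio table; impute or drop first")
    row_d = _euclidean(ratio_table.to_numpy())
    col_d = _euclidean(ratio_table.to_numpy().T)
    return (
        upgma_newick(list(ratio_table.index.astype(str)), row_d),
        upgma_newick(list(ratio_table.columns.astype(str)), col_d),
    )


def _euclidean(X: np.ndarray) -> np.ndarray:
    diff = X[:, None, :] - X[None, :, :]
    return np.sqrt((diff**2).sum(axis=-1))


# ---------------------------------------------------------------------------
# Heatmap export


@dataclass(frozen=True)
class HeatmapConfig:
    vmin: float
    vmax: float
    step: float
    white_below: float

    @property
    def n_bins(self) -> int:
        return int(np.floor((self.vmax - self.vmin) / self.step)) + 1


DEFAULT_HEATMAP_CONFIGS: dict[str, HeatmapConfig] = {
    "C:G>T:A": HeatmapConfig(1.0, 1.573, 0.01, 1.0),
    "C:G>G:C": HeatmapConfig(1.0, 1.802, 0.01, 1.0),
    "C:G>A:T": HeatmapConfig(1.0, 1.362, 0.02, 1.0),
    "fp_fraction": HeatmapConfig(0.01, 0.84, 0.05, 0.01),
}


def gray_bins(values: np.ndarray, cfg: HeatmapConfig) -> np.ndarray:
    """Grayscale bin index per value; -1 (white) below ``white_below``."""
    v = np.asarray(values, dtype=float)
    bins = np.floor((v - cfg.vmin) / cfg.step).astype(int)
    bins = np.clip(bins, 0, cfg.n_bins - 1)
    bins = np.where(v < cfg.white_below, -1, bins)
    return bins


def heatmap_export(
    table: pd.DataFrame,
    cfg: HeatmapConfig,
    tsv_path=None,
    image_path=None,
) -> pd.DataFrame:
    """Bin a value table to gray levels; optionally write TSV and image.

    White (-1) encodes values below ``cfg.white_below``; darker bins encode
    larger values up to ``cfg.vmax`` (clamped).
    """
    bins = pd.DataFrame(
        gray_bins(table.to_numpy(), cfg), index=table.index, columns=table.columns
    )
    if tsv_path is not None:
        bins.to_csv(tsv_path, sep="\t")
    if image_path is not None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        # map: white for -1, then light-to-dark gray
        shade = 1.0 - (bins.to_numpy() + 1) / cfg.n_bins
        shade = np.where(bins.to_numpy() < 0, 1.0, shade)
        fig, ax = plt.subplots(
            figsize=(1 + 0.5 * len(table.columns), 1 + 0.4 * len(table.index))
        )
        ax.imshow(shade, cmap="gray", vmin=0, vmax=1)
        ax.set_xticks(range(len(table.columns)), table.columns, rotation=90)
        ax.set_yticks(range(len(table.index)), table.index)
        fig.tight_layout()
        fig.savefig(image_path, dpi=150)
        plt.close(fig)
    return bins
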