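"""Synthetic genomes, motif-defined context sets, and planted mutation tables.

The generator emulates the two kinds of training/evaluation data the method
needs: (a) context sets of 11-mers around deaminated cytosines, drawn
position-independently from a motif specification (stand-ins for deaminase
mutagenesis datasets); and (b) somatic-mutation tables over a simulated
genome in which a known fraction of mutations is planted into motif-matching
sites, giving ground truth for recovery and calibration tests.

Default enzyme emulations encode the field's qualitative motif structure:
TC for APOBEC1/3A/3B (APOBEC1 with an extra T preference at -3), TC at -2
for APOBEC3C, a wcCCw-like pattern for APOBEC3G, and WRC for AID. They are
synthetic emulations, not experimentally derived matrices.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .context_io import (
    NEIGHBORHOOD_HALFWIDTH,
    Genome,
    MutationRecord,
    write_mutations,
)
from .motif_matrix import (
    BASES,
    WINDOW_LEN,
    ContextWindow,
    FrequencyMatrix,
    WeightMatrix,
    build_weight_matrix,
)

_IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "W": "AT", "R": "AG", "Y": "CT", "S": "CG", "K": "GT", "M": "AC",
}

UPPER_CONSERVATION = 0.9  # strongly informative positions
LOWER_CONSERVATION = 0.7  # weakly informative ("lower case") positions


@dataclass(frozen=True)
class MotifSpec:
    """Per-position base distributions of a mutable motif (center fixed at C)."""

    name: str
    probs: np.ndarray  # (4, 11), columns sum to 1, column 5 = point mass on C

    def __post_init__(self) -> None:
        p = np.asarray(self.probs, dtype=float)
        if p.shape != (4, WINDOW_LEN):
            raise ValueError("probs must have shape (4, 11)")
        if not np.allclose(p.sum(axis=0), 1.0):
            raise ValueError("each position's distribution must sum to 1")
        if not np.allclose(p[:, 5], [0.0, 1.0, 0.0, 0.0]):
            raise ValueError("center position must be a point mass on C")
        object.__setattr__(self, "probs", p)

    @classmethod
    def from_pattern(
        cls,
        name: str,
        informative: Mapping[int, tuple[str, float]],
        background: Sequence[float] = (0.25, 0.25, 0.25, 0.25),
    ) -> "MotifSpec":
        """Build a spec from {offset: (IUPAC letter, conservation)} entries.

        At an informative offset the conservation mass is split equally over
        the letter's bases, the remainder equally over the others; all other
        flank positions take the background distribution.
        """
        probs = np.tile(np.asarray(background, dtype=float)[:, None], (1, WINDOW_LEN))
        for offset, (letter, conservation) in informative.items():
            if offset == 0:
                raise ValueError("offset 0 is the mutated base; it is always C")
            bases = _IUPAC[letter.upper()]
            col = np.full(4, (1.0 - conservation) / (4 - len(bases)))
            for b in bases:
                col[BASES.index(b)] = conservation / len(bases)
            probs[:, offset + 5] = col
        probs[:, 5] = [0.0, 1.0, 0.0, 0.0]
        return cls(name=name, probs=probs)


def default_enzyme_specs() -> dict[str, MotifSpec]:
    """Synthetic emulations of the six deaminase mutable-motif structures."""
    U, L = UPPER_CONSERVATION, LOWER_CONSERVATION
    return {
        "APOBEC1": MotifSpec.from_pattern(
            "APOBEC1", {-1: ("T", U), -3: ("T", L)}
        ),
        "APOBEC3A": MotifSpec.from_pattern("APOBEC3A", {-1: ("T", U)}),
        "APOBEC3B": MotifSpec.from_pattern("APOBEC3B", {-1: ("T", U)}),
        "APOBEC3C": MotifSpec.from_pattern("APOBEC3C", {-2: ("T", U)}),
        "APOBEC3G": MotifSpec.from_pattern(
            "APOBEC3G",
            {-1: ("C", U), -2: ("C", L), -3: ("W", L), 1: ("W", L)},
        ),
        "AID": MotifSpec.from_pattern("AID", {-2: ("W", U), -1: ("R", U)}),
    }


def weight_matrix_from_spec(
    spec: MotifSpec, pseudo_n: int = 10_000, label: str | None = None
) -> WeightMatrix:
    """The weight matrix a large training set drawn from ``spec`` would yield."""
    fm = FrequencyMatrix(counts=spec.probs * pseudo_n, n_sequences=pseudo_n)
    return build_weight_matrix(fm, label=label if label is not None else spec.name)


def simulate_genome(
    length: int,
    base_probs: Sequence[float] = (0.25, 0.25, 0.25, 0.25),
    seed: int = 0,
    name: str = "chr1",
) -> Genome:
    """An i.i.d. random genome; deterministic per seed."""
    if length < 2 * NEIGHBORHOOD_HALFWIDTH + 1:
        raise ValueError(f"genome length must be at least {2 * NEIGHBORHOOD_HALFWIDTH + 1}")
    p = np.asarray(base_probs, dtype=float)
    if not np.isclose(p.sum(), 1.0):
        raise ValueError("base_probs must sum to 1")
    rng = np.random.default_rng(seed)
    codes = rng.choice(4, size=length, p=p)
    seq = "".join(BASES[c] for c in codes)
    return Genome({name: seq})


def simulate_context_set(
    spec: MotifSpec, n: int, seed: int = 0
) -> list[ContextWindow]:
    """n 11-mers drawn position-independently from the motif spec."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    cols = np.empty((n, WINDOW_LEN), dtype=np.int64)
    for j in range(WINDOW_LEN):
        cols[:, j] = rng.choice(4, size=n, p=spec.probs[:, j])
    return [ContextWindow("".join(BASES[c] for c in row)) for row in cols]


@dataclass
class PlantedDataset:
    """A mutation table with known motif-planted ground truth."""

    genome: Genome
    records: list[MutationRecord]
    truth: pd.DataFrame  # chrom, pos, origin (planted|uniform), score
    planted_fraction: float
    motif_name: str
    subclass_mix: dict[str, float]
    seed: int

    def to_files(self, genome_path, mutations_path, truth_path) -> None:
        self.genome.to_fasta(genome_path)
        write_mutations(self.records, mutations_path)
        self.truth.to_csv(truth_path, sep="\t", index=False)


_ALT_FOR_CLASS_C = {"C:G>T:A": "T", "C:G>G:C": "G", "C:G>A:T": "A"}
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def _eligible_sites(genome: Genome) -> list[tuple[str, int]]:
    """C/G positions with a full 121-bp neighborhood inside a contig."""
    sites: list[tuple[str, int]] = []
    h = NEIGHBORHOOD_HALFWIDTH
    for name in genome.names():
        seq = genome.sequence(name)
        arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
        is_cg = (arr == ord("C")) | (arr == ord("G"))
        idxs = np.nonzero(is_cg)[0]
        idxs = idxs[(idxs >= h) & (idxs < len(seq) - h)]
        sites.extend((name, int(i)) for i in idxs)
    return sites


def simulate_mutation_dataset(
    genome: Genome,
    wm_or_spec: WeightMatrix | MotifSpec,
    planted_fraction: float,
    n: int,
    subclass_mix: Mapping[str, float] | None = None,
    seed: int = 0,
    tissue: str = "synthetic",
    sample_id: str = "s1",
) -> PlantedDataset:
    """Plant ``planted_fraction`` of n mutations into motif-matching C/G sites.

    Planted sites are drawn without replacement with probability proportional
    to 2^S, where S is the site's matching score (in bits) under the motif's
    weight matrix — a Boltzmann weighting that produces a smooth, tunable
    enrichment. The remaining mutations are drawn uniformly from the leftover
    eligible C/G sites. Every mutation's true origin is kept in the truth
    sidecar.
    """
    if not 0.0 <= planted_fraction <= 1.0:
        raise ValueError("planted_fraction must be in [0, 1]")
    if subclass_mix is None:
        subclass_mix = {"C:G>T:A": 1.0}
    mix_classes = list(subclass_mix)
    mix_p = np.asarray([subclass_mix[c] for c in mix_classes], dtype=float)
    if not np.isclose(mix_p.sum(), 1.0):
        raise ValueError("subclass_mix must sum to 1")
    if isinstance(wm_or_spec, MotifSpec):
        wm = weight_matrix_from_spec(wm_or_spec)
        motif_name = wm_or_spec.name
    else:
        wm = wm_or_spec
        motif_name = wm.label or "matrix"

    sites = _eligible_sites(genome)
    if len(sites) < n:
        raise ValueError(f"genome has only {len(sites)} eligible C/G sites, need {n}")
    rng = np.random.default_rng(seed)

    scores = _site_scores(genome, wm, sites)
    n_planted = int(rng.binomial(n, planted_fraction))
    site_idx = np.arange(len(sites))
    boltz = np.exp2(scores - scores.max())
    boltz /= boltz.sum()
    planted_idx = rng.choice(site_idx, size=n_planted, replace=False, p=boltz)
    remaining = np.setdiff1d(site_idx, planted_idx, assume_unique=False)
    uniform_idx = rng.choice(remaining, size=n - n_planted, replace=False)

    chosen = np.concatenate([planted_idx, uniform_idx])
    origins = ["planted"] * n_planted + ["uniform"] * (n - n_planted)
    classes = [mix_classes[k] for k in rng.choice(len(mix_classes), size=n, p=mix_p)]

    records: list[MutationRecord] = []
    truth_rows: list[dict] = []
    for k, origin, subclass in zip(chosen, origins, classes):
        name, idx = sites[k]
        ref = genome.sequence(name)[idx]
        alt = _ALT_FOR_CLASS_C[subclass]
        if ref == "G":
            alt = _COMP[alt]
        records.append(
            MutationRecord(
                sample_id=sample_id, chrom=name, pos=idx + 1,
                ref=ref, alt=alt, tissue=tissue,
            )
        )
        truth_rows.append(
            {"chrom": name, "pos": idx + 1, "origin": origin, "score": float(scores[k])}
        )
    order = np.argsort([r.pos for r in records], kind="stable")
    records = [records[i] for i in order]
    truth = pd.DataFrame([truth_rows[i] for i in order])
    return PlantedDataset(
        genome=genome,
        records=records,
        truth=truth,
        planted_fraction=planted_fraction,
        motif_name=motif_name,
        subclass_mix=dict(subclass_mix),
        seed=seed,
    )


def _site_scores(
    genome: Genome, wm: WeightMatrix, sites: Sequence[tuple[str, int]]
) -> np.ndarray:
    """Matching scores (bits) of strand-normalized windows at genomic C/G sites."""
    from numpy.lib.stride_tricks import sliding_window_view

    from .motif_matrix import encode_bases

    cols = np.asarray(wm.scoring_columns)
    scores = np.empty(len(sites))
    by_chrom: dict[str, list[int]] = {}
    for i, (name, _) in enumerate(sites):
        by_chrom.setdefault(name, []).append(i)
    for name, rows in by_chrom.items():
        codes = encode_bases(genome.sequence(name))
        idxs = np.array([sites[i][1] for i in rows])
        wins = sliding_window_view(codes, WINDOW_LEN)[idxs - 5].copy()
        is_g = codes[idxs] == 2
        if np.any(is_g):
            wins[is_g] = (3 - wins[is_g])[:, ::-1]
        scores[np.array(rows)] = wm.W[wins[:, cols], cols].sum(axis=-1)
    return scores
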