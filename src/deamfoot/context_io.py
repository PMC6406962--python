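"""Genome and mutation-table I/O; context and neighborhood extraction.

Coordinates: mutation tables carry 1-based positions (COSMIC convention);
internally all arithmetic is 0-based half-open. Strand collapse: because the
mutated strand is unknown, complementary substitutions are pooled into six
classes (e.g. C>T and G>A are both C:G>T:A), and every extracted context is
normalized so its center base is the pyrimidine C.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .motif_matrix import ContextWindow, reverse_complement

NEIGHBORHOOD_HALFWIDTH = 60
NEIGHBORHOOD_LEN = 2 * NEIGHBORHOOD_HALFWIDTH + 1  # 121
CENTER_OFFSET = NEIGHBORHOOD_HALFWIDTH  # 60, the 61st base

MUTATION_COLUMNS = ["sample", "chrom", "pos", "ref", "alt", "tissue"]

_PYRIMIDINE_CLASS = {
    ("C", "T"): "C:G>T:A",
    ("C", "G"): "C:G>G:C",
    ("C", "A"): "C:G>A:T",
    ("T", "C"): "T:A>C:G",
    ("T", "G"): "T:A>G:C",
    ("T", "A"): "T:A>A:T",
}
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def substitution_class(ref: str, alt: str) -> str:
    """One of the six strand-collapsed substitution classes."""
    ref, alt = ref.upper(), alt.upper()
    if ref in "CT":
        key = (ref, alt)
    else:
        key = (_COMP[ref], _COMP[alt])
    if key not in _PYRIMIDINE_CLASS:
        raise ValueError(f"invalid substitution {ref}>{alt}")
    return _PYRIMIDINE_CLASS[key]


CG_CLASSES = ("C:G>T:A", "C:G>G:C", "C:G>A:T")


class Genome:
    """Named uppercase sequences over {A,C,G,T,N} with O(slice) random access."""

    def __init__(self, sequences: dict[str, str]):
        if not sequences:
            raise ValueError("empty genome")
        self._seqs = {name: seq.upper().replace("U", "T") for name, seq in sequences.items()}
        self.lengths = {name: len(seq) for name, seq in self._seqs.items()}

    @classmethod
    def from_fasta(cls, path) -> "Genome":
        from Bio import SeqIO

        seqs: dict[str, str] = {}
        for rec in SeqIO.parse(str(path), "fasta"):
            if rec.id in seqs:
                raise ValueError(f"duplicate sequence name {rec.id!r} in FASTA")
            seqs[rec.id] = str(rec.seq)
        if not seqs:
            raise ValueError(f"no sequences found in {path}")
        return cls(seqs)

    def to_fasta(self, path, width: int = 70) -> None:
        with open(path, "w") as fh:
            for name, seq in self._seqs.items():
                fh.write(f">{name}\n")
                for i in range(0, len(seq), width):
                    fh.write(seq[i : i + width] + "\n")

    def names(self) -> list[str]:
        return list(self._seqs)

    def sequence(self, name: str) -> str:
        return self._seqs[name]

    def slice(self, name: str, start0: int, end0: int) -> str:
        """0-based half-open slice; raises if out of bounds."""
        seq = self._seqs[name]
        if start0 < 0 or end0 > len(seq):
            raise IndexError(f"slice [{start0},{end0}) outside {name} (len {len(seq)})")
        return seq[start0:end0]

    def base(self, name: str, pos1: int) -> str:
        return self.slice(name, pos1 - 1, pos1)

    def reverse_complemented(self) -> "Genome":
        return Genome({name: reverse_complement(seq) for name, seq in self._seqs.items()})


@dataclass(frozen=True)
class MutationRecord:
    """One somatic single-base substitution (1-based genomic position)."""

    sample_id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    tissue: str

    @property
    def subclass(self) -> str:
        return substitution_class(self.ref, self.alt)


@dataclass(frozen=True)
class Neighborhood:
    """121-base sequence centered on the mutated base (offset 60)."""

    seq: str
    chrom: str
    start0: int  # 0-based start of the neighborhood in the genome

    def __post_init__(self) -> None:
        if len(self.seq) != NEIGHBORHOOD_LEN:
            raise ValueError(f"neighborhood must have length {NEIGHBORHOOD_LEN}")

    @property
    def center_base(self) -> str:
        return self.seq[CENTER_OFFSET]


def read_mutations(
    path, genome: Genome
) -> tuple[list[MutationRecord], pd.DataFrame]:
    """Read and validate a mutation TSV against a genome.

    Returns (records, rejection_report). Every input row lands either in the
    record list or in the report, whose columns are the input row index, the
    rejection reason and the row's (chrom, pos). Reasons: ``unknown_chrom``,
    ``bad_allele``, ``ref_mismatch``, ``edge`` (within 60 bp of a contig
    end), ``ambiguous`` (N in the 121-bp neighborhood).
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "sample": str})
    missing = [c for c in MUTATION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"mutation table missing columns: {missing}")
    records: list[MutationRecord] = []
    rejects: list[dict] = []
    for idx, row in df.iterrows():
        reason = _validate_row(row, genome)
        if reason is None:
            records.append(
                MutationRecord(
                    sample_id=str(row["sample"]),
                    chrom=str(row["chrom"]),
                    pos=int(row["pos"]),
                    ref=str(row["ref"]).upper(),
                    alt=str(row["alt"]).upper(),
                    tissue=str(row["tissue"]),
                )
            )
        else:
            rejects.append(
                {"row": idx, "reason": reason, "chrom": row.get("chrom"), "pos": row.get("pos")}
            )
    report = pd.DataFrame(rejects, columns=["row", "reason", "chrom", "pos"])
    return records, report


def _validate_row(row, genome: Genome) -> str | None:
    chrom = str(row["chrom"])
    if chrom not in genome.lengths:
        return "unknown_chrom"
    ref, alt = str(row["ref"]).upper(), str(row["alt"]).upper()
    if ref not in "ACGT" or alt not in "ACGT" or ref == alt:
        return "bad_allele"
    pos = int(row["pos"])
    length = genome.lengths[chrom]
    if pos < 1 or pos > length:
        return "unknown_chrom"
    if genome.base(chrom, pos) != ref:
        return "ref_mismatch"
    if pos - 1 < NEIGHBORHOOD_HALFWIDTH or pos - 1 + NEIGHBORHOOD_HALFWIDTH >= length:
        return "edge"
    nb = genome.slice(chrom, pos - 1 - NEIGHBORHOOD_HALFWIDTH, pos + NEIGHBORHOOD_HALFWIDTH)
    if "N" in nb:
        return "ambiguous"
    return None


def write_mutations(records: Iterable[MutationRecord], path) -> None:
    rows = [
        {
            "sample": r.sample_id,
            "chrom": r.chrom,
            "pos": r.pos,
            "ref": r.ref,
            "alt": r.alt,
            "tissue": r.tissue,
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=MUTATION_COLUMNS).to_csv(path, sep="\t", index=False)


def extract_window(
    genome: Genome, rec: MutationRecord, halfwidth: int = 5
) -> ContextWindow:
    """The strand-normalized 11-mer around a C:G mutation.

    If the genome shows G at the mutated position, the reverse complement is
    returned so the center is always C, with origin_strand = '-'.
    """
    if rec.ref not in "CG":
        raise ValueError(f"deaminase context requires a C:G site, got ref={rec.ref}")
    idx = rec.pos - 1
    seq = genome.slice(rec.chrom, idx - halfwidth, idx + halfwidth + 1)
    if "N" in seq:
        raise ValueError("ambiguous context (N in window)")
    if rec.ref == "G":
        return ContextWindow(reverse_complement(seq), origin_strand="-")
    return ContextWindow(seq, origin_strand="+")


def extract_neighborhood(genome: Genome, rec: MutationRecord) -> Neighborhood:
    """The 121-bp neighborhood centered on the mutation; rejects edge records."""
    idx = rec.pos - 1
    length = genome.lengths[rec.chrom]
    if idx < NEIGHBORHOOD_HALFWIDTH or idx + NEIGHBORHOOD_HALFWIDTH >= length:
        raise ValueError("edge: mutation within 60 bp of a contig end")
    seq = genome.slice(rec.chrom, idx - NEIGHBORHOOD_HALFWIDTH, idx + NEIGHBORHOOD_HALFWIDTH + 1)
    nb = Neighborhood(seq=seq, chrom=rec.chrom, start0=idx - NEIGHBORHOOD_HALFWIDTH)
    if nb.center_base != rec.ref:
        raise ValueError("neighborhood center does not match the record's ref allele")
    return nb


def eligible_background_sites(nb: Neighborhood, halfwidth: int = 5) -> np.ndarray:
    """Offsets of non-mutated C/G sites in the neighborhood with full context.

    Only C- or G-centered positions are scoreable by the C-centered matrices
    (G via reverse complement); the site must carry a full +-5 window inside
    the neighborhood (offsets 5..115) and the mutated center (offset 60) is
    excluded.
    """
    arr = np.frombuffer(nb.seq.encode("ascii"), dtype=np.uint8)
    is_cg = (arr == ord("C")) | (arr == ord("G"))
    offsets = np.nonzero(is_cg)[0]
    offsets = offsets[
        (offsets >= halfwidth)
        & (offsets < NEIGHBORHOOD_LEN - halfwidth)
        & (offsets != CENTER_OFFSET)
    ]
    return offsets


def window_at_offset(nb: Neighborhood, offset: int, halfwidth: int = 5) -> ContextWindow:
    """Strand-normalized window around a C/G site inside a neighborhood."""
    seq = nb.seq[offset - halfwidth : offset + halfwidth + 1]
    if nb.seq[offset] == "G":
        return ContextWindow(reverse_complement(seq), origin_strand="-")
    return ContextWindow(seq, origin_strand="+")


def shuffle_context(window: ContextWindow, rng: np.random.Generator) -> ContextWindow:
    """Permute the 10 flanking bases, keeping the mutated center fixed.

    Preserves each sequence's base composition exactly, as in the shuffled-
    sites control.
    """
    fl = list(window.flanks)
    perm = rng.permutation(10)
    shuffled = [fl[i] for i in perm]
    bases = "".join(shuffled[:5]) + window.center + "".join(shuffled[5:])
    return ContextWindow(bases, origin_strand=window.origin_strand)


def _composition(windows: Sequence[ContextWindow]) -> np.ndarray:
    """Mononucleotide composition over all bases of a window set, order A,C,G,T."""
    joined = "".join(w.bases for w in windows)
    total = len(joined)
    return np.array([joined.count(b) / total for b in "ACGT"])


def sample_matched_sites(
    genome: Genome,
    template: Sequence[ContextWindow],
    rng: np.random.Generator,
    tol: float = 0.01,
    max_attempts: int = 1000,
    t_alpha: float = 0.05,
) -> list[ContextWindow]:
    """Random C/G-centered windows matching a template set's composition.

    Draws ``len(template)`` strand-normalized windows at random C/G genomic
    sites, accepting a draw only when (a) every base's set-level frequency is
    within ``tol`` of the template's and (b) a 2-tailed t-test on per-window
    A+T fraction finds no significant difference (p >= ``t_alpha``); otherwise
    the sampling is repeated, up to ``max_attempts`` times.
    """
    n = len(template)
    if n == 0:
        raise ValueError("empty template set")
    target = _composition(template)
    template_at = np.array([w.at_fraction() for w in template])
    sites = _cg_site_index(genome)
    if len(sites) < n:
        raise ValueError("genome too small for the requested sample size")

    def _window_at(k: int) -> ContextWindow | None:
        name, idx = sites[k]
        seq = genome.slice(name, idx - 5, idx + 6)
        if "N" in seq:
            return None
        if seq[5] == "G":
            return ContextWindow(reverse_complement(seq), origin_strand="-")
        return ContextWindow(seq, origin_strand="+")

    def _counts(w: ContextWindow) -> np.ndarray:
        return np.array([w.bases.count(b) for b in "ACGT"], dtype=float)

    total_bases = n * 11
    for _ in range(max_attempts):
        pick = list(rng.choice(len(sites), size=n, replace=False))
        windows = [_window_at(k) for k in pick]
        if any(w is None for w in windows):
            continue
        counts = np.stack([_counts(w) for w in windows])  # (n, 4)
        col = counts.sum(axis=0)

        def _err(c: np.ndarray) -> tuple[float, float]:
            dev = np.abs(c / total_bases - target)
            return float(dev.max()), float(dev.sum())

        # local search: random single-window swaps that reduce the worst
        # composition deviation, until every base is within tol
        err = _err(col)
        for _ in range(200 * n):
            if err[0] <= tol:
                break
            k_new = int(rng.integers(len(sites)))
            w_new = _window_at(k_new)
            if w_new is None:
                continue
            r = int(rng.integers(n))
            c_new = _counts(w_new)
            col_try = col - counts[r] + c_new
            err_try = _err(col_try)
            if err_try < err:
                windows[r] = w_new
                counts[r] = c_new
                col = col_try
                err = err_try
        if err[0] > tol:
            continue
        sample_at = np.array([w.at_fraction() for w in windows])
        if template_at.std() == 0 and sample_at.std() == 0:
            p = 1.0 if np.isclose(template_at.mean(), sample_at.mean()) else 0.0
        else:
            p = stats.ttest_ind(template_at, sample_at, equal_var=False).pvalue
        if p < t_alpha:
            continue  # significant composition difference: redraw entirely
        return windows
    raise ValueError("composition unmatchable: no acceptable sample found")


def _cg_site_index(genome: Genome) -> list[tuple[str, int]]:
    """All (name, 0-based index) C/G positions with a full +-5 window."""
    sites: list[tuple[str, int]] = []
    for name in genome.names():
        seq = genome.sequence(name)
        arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
        is_cg = (arr == ord("C")) | (arr == ord("G"))
        idxs = np.nonzero(is_cg)[0]
        idxs = idxs[(idxs >= 5) & (idxs < len(seq) - 5)]
        sites.extend((name, int(i)) for i in idxs)
    return sites


def at_content_filter(
    windows: Sequence[ContextWindow], threshold: float = 0.5
) -> tuple[list[ContextWindow], np.ndarray]:
    """Remove A/T-rich contexts: flanking A+T fraction >= threshold (inclusive).

    Returns (kept_windows, keep_mask) so callers can filter paired record
    lists with the same mask. A/T-rich motifs inflate false positives in
    A/T-rich mutation sets, hence the filter.
    """
    mask = np.array([w.at_fraction() < threshold for w in windows])
    kept = [w for w, m in zip(windows, mask) if m]
    return kept, mask


def windows_to_bed(
    records: Sequence[MutationRecord], path, halfwidth: int = 5
) -> None:
    """BED (0-based half-open) of the analyzed context windows."""
    with open(path, "w") as fh:
        for r in records:
            fh.write(f"{r.chrom}\t{r.pos - 1 - halfwidth}\t{r.pos + halfwidth}\t{r.sample_id}\n")
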