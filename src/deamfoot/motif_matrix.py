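"""Nucleotide weight matrices (sequence profiles) of deaminase mutable motifs.

A mutable motif is represented as a mononucleotide profile over an 11-base
window centered on the mutated cytosine (positions -5..+5, 0 = mutated base).
From a set of aligned, strand-normalized mutation contexts we build:

* a :class:`FrequencyMatrix` of per-position base counts/frequencies,
* a :class:`BackgroundModel` e(b) taken as the mean base frequency of the
  four outermost, least informative positions (-5, -4, +4, +5),
* a :class:`WeightMatrix` of log-odds W(b, j) = log2[f(b, j) / e(b)].

A window's matching score is the sum of its log-odds over the scoring
positions (default -3..+3); the *percent matching score* ("weight") rescales
it affinely to [0, 100] between the minimal and maximal achievable scores.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

BASES = "ACGT"
WINDOW_LEN = 11
OFFSETS = tuple(range(-5, 6))  # 0 = mutated base
FLANK_OFFSETS = tuple(j for j in OFFSETS if j != 0)
BACKGROUND_OFFSETS = (-5, -4, 4, 5)
DEFAULT_SCORING_POSITIONS = tuple(range(-3, 4))

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")

_BASE_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(BASES):
    _BASE_CODE[ord(_b)] = _i


class DegenerateMatrixError(ValueError):
    """Raised when Smax == Smin and the percent score is undefined."""


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def encode_bases(seq: str) -> np.ndarray:
    """Map A,C,G,T to 0..3 (uint8). Any other character maps to 255."""
    return _BASE_CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


@dataclass(frozen=True)
class ContextWindow:
    """An 11-mer centered on a strand-normalized mutated base.

    ``origin_strand`` records whether the window was reverse-complemented
    during extraction ('-' means the genome showed the complementary strand).
    """

    bases: str
    origin_strand: str = "+"

    def __post_init__(self) -> None:
        if len(self.bases) != WINDOW_LEN:
            raise ValueError(
                f"context window must have length {WINDOW_LEN}, got {len(self.bases)}"
            )
        if not set(self.bases) <= set(BASES):
            raise ValueError(f"ambiguous base in context window {self.bases!r}")
        if self.origin_strand not in "+-":
            raise ValueError("origin_strand must be '+' or '-'")

    @property
    def center(self) -> str:
        return self.bases[5]

    @property
    def flanks(self) -> str:
        """The 10 flanking bases (center excluded)."""
        return self.bases[:5] + self.bases[6:]

    def at_fraction(self) -> float:
        """Fraction of A/T among the 10 flanking bases."""
        fl = self.flanks
        return (fl.count("A") + fl.count("T")) / 10.0


def _as_window(w: ContextWindow | str) -> ContextWindow:
    return w if isinstance(w, ContextWindow) else ContextWindow(str(w))


@dataclass
class FrequencyMatrix:
    """Per-position base counts and frequencies of a context set."""

    counts: np.ndarray  # shape (4, 11), rows A,C,G,T
    n_sequences: int

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape != (4, WINDOW_LEN):
            raise ValueError("counts must have shape (4, 11)")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")

    @property
    def frequencies(self) -> np.ndarray:
        return self.counts / self.n_sequences


@dataclass
class BackgroundModel:
    """Expected base frequencies e(b), rows ordered A,C,G,T."""

    e: np.ndarray

    def __post_init__(self) -> None:
        self.e = np.asarray(self.e, dtype=float)
        if self.e.shape != (4,):
            raise ValueError("background must have 4 entries")
        if np.any(self.e < 0) or not np.isclose(self.e.sum(), 1.0):
            raise ValueError("background frequencies must be non-negative and sum to 1")


@dataclass
class WeightMatrix:
    """Log-odds table W(b, j) in bits with score bounds over the scoring window."""

    W: np.ndarray  # shape (4, 11)
    scoring_positions: tuple[int, ...] = DEFAULT_SCORING_POSITIONS
    pseudocount: float = 0.5
    label: str = ""
    smin: float = field(init=False)
    smax: float = field(init=False)

    def __post_init__(self) -> None:
        self.W = np.asarray(self.W, dtype=float)
        if self.W.shape != (4, WINDOW_LEN):
            raise ValueError("W must have shape (4, 11)")
        if not np.all(np.isfinite(self.W)):
            raise ValueError("W must be finite everywhere")
        self.scoring_positions = tuple(sorted(self.scoring_positions))
        cols = self.scoring_columns
        self.smin = float(self.W[:, cols].min(axis=0).sum())
        self.smax = float(self.W[:, cols].max(axis=0).sum())
        if not self.smax > self.smin:
            raise DegenerateMatrixError(
                "degenerate matrix: Smax == Smin, percent score undefined"
            )

    @property
    def scoring_columns(self) -> list[int]:
        return [j + 5 for j in self.scoring_positions]


def count_contexts(windows: Iterable[ContextWindow | str]) -> FrequencyMatrix:
    """Tabulate per-position base counts of a set of strand-normalized 11-mers."""
    ws = [_as_window(w) for w in windows]
    if not ws:
        raise ValueError("no training contexts")
    codes = np.stack([encode_bases(w.bases) for w in ws])  # (n, 11)
    counts = np.zeros((4, WINDOW_LEN))
    for b in range(4):
        counts[b] = (codes == b).sum(axis=0)
    return FrequencyMatrix(counts=counts, n_sequences=len(ws))


def background_frequencies(fm: FrequencyMatrix) -> BackgroundModel:
    """e(b): mean base frequency over the outer flank positions -5,-4,+4,+5."""
    cols = [j + 5 for j in BACKGROUND_OFFSETS]
    e = fm.frequencies[:, cols].mean(axis=1)
    return BackgroundModel(e=e)


def build_weight_matrix(
    fm: FrequencyMatrix,
    bg: BackgroundModel | None = None,
    pseudocount: float = 0.5,
    scoring_positions: Sequence[int] = DEFAULT_SCORING_POSITIONS,
    label: str = "",
) -> WeightMatrix:
    """W(b, j) = log2[f(b, j) / e(b)], smoothed so the log-odds stay finite.

    A pseudocount (default 0.5, Jeffreys-style) is added to each count before
    computing frequencies; the background is floored at 1/(4*n_sequences) and
    renormalized. Both smoothing choices vanish as the training set grows.
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    if bg is None:
        bg = background_frequencies(fm)
    n = fm.n_sequences
    f_s = (fm.counts + pseudocount) / (n + 4 * pseudocount)
    e_s = np.maximum(bg.e, 1.0 / (4.0 * n))
    e_s = e_s / e_s.sum()
    W = np.log2(f_s / e_s[:, None])
    return WeightMatrix(
        W=W,
        scoring_positions=tuple(scoring_positions),
        pseudocount=pseudocount,
        label=label,
    )


def _scoring_codes(wm: WeightMatrix, window: ContextWindow | str) -> np.ndarray:
    """Base codes of the window restricted to the scoring positions.

    Accepts either a full 11-mer or a sequence already aligned to the scoring
    window (e.g. a 7-mer for the default -3..+3 window).
    """
    bases = window.bases if isinstance(window, ContextWindow) else str(window)
    k = len(wm.scoring_positions)
    if len(bases) == WINDOW_LEN:
        codes = encode_bases(bases)[wm.scoring_columns]
    elif len(bases) == k:
        codes = encode_bases(bases)
    else:
        raise ValueError(
            f"window length must be {WINDOW_LEN} or {k}, got {len(bases)}"
        )
    if np.any(codes == 255):
        raise ValueError(f"ambiguous base in scoring window of {bases!r}")
    return codes


def matching_score(wm: WeightMatrix, window: ContextWindow | str) -> float:
    """Summed log-odds S = sum_j W(b_j, j) over the scoring positions."""
    codes = _scoring_codes(wm, window)
    return float(wm.W[codes, wm.scoring_columns].sum())


def score_codes(wm: WeightMatrix, codes: np.ndarray) -> np.ndarray:
    """Vectorized matching scores for pre-encoded scoring windows.

    ``codes`` has shape (..., k) with k = number of scoring positions; values
    are base codes 0..3 already aligned to the scoring window.
    """
    cols = np.asarray(wm.scoring_columns)
    return wm.W[codes, cols].sum(axis=-1)


def percent_from_scores(wm: WeightMatrix, scores: np.ndarray | float):
    return 100.0 * (np.asarray(scores, dtype=float) - wm.smin) / (wm.smax - wm.smin)


def percent_score(wm: WeightMatrix, window: ContextWindow | str) -> float:
    """Percent matching score ("weight") in [0, 100]."""
    return float(percent_from_scores(wm, matching_score(wm, window)))


def information_content(fm: FrequencyMatrix) -> tuple[np.ndarray, str]:
    """Per-position information content in bits and a cased consensus string.

    IC(j) = 2 + sum_b f(b,j) log2 f(b,j), with 0*log(0) := 0. The consensus
    letter is the most frequent base: upper case when IC >= 1 bit, lower case
    when 0.25 <= IC < 1 bit, '.' below that.
    """
    f = fm.frequencies
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(f > 0, f * np.log2(np.where(f > 0, f, 1.0)), 0.0)
    ic = 2.0 + plogp.sum(axis=0)
    ic = np.clip(ic, 0.0, 2.0)
    letters = []
    for j in range(WINDOW_LEN):
        b = BASES[int(f[:, j].argmax())]
        if ic[j] >= 1.0:
            letters.append(b)
        elif ic[j] >= 0.25:
            letters.append(b.lower())
        else:
            letters.append(".")
    return ic, "".join(letters)


def logo_table(fm: FrequencyMatrix) -> pd.DataFrame:
    """Per-position IC and per-base letter heights (f * IC), logo-tool ready."""
    ic, consensus = information_content(fm)
    f = fm.frequencies
    df = pd.DataFrame(
        {
            "position": OFFSETS,
            "position_1based": range(1, WINDOW_LEN + 1),
            "ic_bits": ic,
            "consensus": list(consensus),
        }
    )
    for i, b in enumerate(BASES):
        df[f"height_{b}"] = f[i] * ic
    return df


@dataclass
class Chi2Comparison:
    """Summed per-position contingency chi-square between two context sets."""

    chi2: float
    df: int
    p: float
    low_expected: bool  # any expected cell < 1 after dropping empty bases


def compare_matrices_chi2(
    set_a: Iterable[ContextWindow | str],
    set_b: Iterable[ContextWindow | str],
    df: int | None = None,
) -> Chi2Comparison:
    """Compare the raw nucleotide counts of two context sets position by position.

    For each of the 10 flanking positions (the constant center is excluded) a
    2x4 contingency table of raw counts is formed; the chi-square statistics
    are summed over positions. The default degrees of freedom are structural,
    (positions) x (bases - 1) = 30; pass ``df`` to override (e.g. 42).
    """
    fa = count_contexts(set_a)
    fb = count_contexts(set_b)
    flank_cols = [j + 5 for j in FLANK_OFFSETS]
    stat = 0.0
    low_expected = False
    for c in flank_cols:
        table = np.stack([fa.counts[:, c], fb.counts[:, c]])  # (2, 4)
        keep = table.sum(axis=0) > 0
        table = table[:, keep]
        total = table.sum()
        expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / total
        if np.any(expected < 1):
            low_expected = True
        stat += float(((table - expected) ** 2 / expected).sum())
    if df is None:
        df = len(flank_cols) * (len(BASES) - 1)
    p = float(stats.chi2.sf(stat, df)) if stat > 0 else 1.0
    return Chi2Comparison(chi2=stat, df=df, p=p, low_expected=low_expected)


def chi2_critical_value(alpha: float, n_comparisons: int, df: int) -> float:
    """Bonferroni-corrected chi-square critical value for a family of comparisons."""
    return float(stats.chi2.isf(alpha / n_comparisons, df))


# ---------------------------------------------------------------------------
# Serialization


def write_matrix_tsv(wm: WeightMatrix, path_or_buf) -> None:
    """Matrix TSV: '#key=value' metadata, a position header, 4 base rows."""
    buf = io.StringIO()
    buf.write(f"#pseudocount={wm.pseudocount}\n")
    buf.write(f"#scoring_positions={','.join(map(str, wm.scoring_positions))}\n")
    buf.write(f"#smin={wm.smin!r}\n")
    buf.write(f"#smax={wm.smax!r}\n")
    buf.write(f"#label={wm.label}\n")
    header = ["base"] + [f"{j}({j + 6})" for j in OFFSETS]  # -5..+5 and 1..11 labels
    buf.write("\t".join(header) + "\n")
    for i, b in enumerate(BASES):
        buf.write("\t".join([b] + [repr(float(x)) for x in wm.W[i]]) + "\n")
    text = buf.getvalue()
    if hasattr(path_or_buf, "write"):
        path_or_buf.write(text)
    else:
        with open(path_or_buf, "w") as fh:
            fh.write(text)


def read_matrix_tsv(path) -> WeightMatrix:
    meta: dict[str, str] = {}
    rows: dict[str, list[float]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                key, _, val = line[1:].partition("=")
                meta[key] = val
            else:
                parts = line.split("\t")
                if parts[0] == "base":
                    continue
                rows[parts[0]] = [float(x) for x in parts[1:]]
    W = np.array([rows[b] for b in BASES])
    scoring = tuple(int(x) for x in meta["scoring_positions"].split(","))
    return WeightMatrix(
        W=W,
        scoring_positions=scoring,
        pseudocount=float(meta.get("pseudocount", 0.5)),
        label=meta.get("label", ""),
    )


def read_context_set(path) -> list[ContextWindow]:
    """Read 11-mers from plain text (one per line, '#' comments) or FASTA."""
    with open(path) as fh:
        first = fh.read(1)
    if first == ">":
        from Bio import SeqIO

        return [
            ContextWindow(str(rec.seq).upper()) for rec in SeqIO.parse(path, "fasta")
        ]
    windows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            windows.append(ContextWindow(line.split("\t")[0].upper()))
    return windows


def write_context_set(windows: Iterable[ContextWindow], path) -> None:
    with open(path, "w") as fh:
        for w in windows:
            fh.write(f"{_as_window(w).bases}\n")
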