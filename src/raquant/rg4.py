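"""RNA G-quadruplex (rG4) motif scanning of mRNA transcripts.

Canonical rG4 motifs are four guanine tracts (G-tracts) of at least
``min_tract_len`` consecutive Gs separated by three loops of 1-7 nt.  The
scanner finds maximal G-runs, chains them leftmost-greedily into
non-overlapping four-tract motifs, scores each motif with a deterministic
G4Hunter-style window score (a stand-in for neural rG4 probability
predictors, on the same [0, 1] scale with the same >= 0.5 default positivity
threshold), assigns the motif to the 5'UTR / CDS / 3'UTR region holding the
majority of its span, and aggregates per-gene profiles into the cohort-level
structural summaries used to characterise an rG4-positive gene set.

Coordinates are 0-based half-open throughout.  Input sequences may be DNA or
RNA; U is mapped to T internally and N never participates in a run.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import pandas as pd

from ._util import normalize_sequence, percent

REGIONS = ("5UTR", "CDS", "3UTR")


@dataclass(frozen=True)
class Transcript:
    """A gene's mRNA with its 5'UTR / CDS / 3'UTR spans (half-open, 0-based).

    Spans must tile the sequence in order: utr5 starts at 0, utr3 ends at the
    sequence length, and consecutive spans abut.  Any span may be empty.
    """

    gene_symbol: str
    sequence: str
    utr5: tuple[int, int]
    cds: tuple[int, int]
    utr3: tuple[int, int]

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", normalize_sequence(self.sequence))
        n = len(self.sequence)
        spans = (self.utr5, self.cds, self.utr3)
        for name, (s, e) in zip(("utr5", "cds", "utr3"), spans):
            if not (0 <= s <= e <= n):
                raise ValueError(f"{self.gene_symbol}: invalid {name} span ({s}, {e})")
        if self.utr5[0] != 0 or self.utr3[1] != n:
            raise ValueError(f"{self.gene_symbol}: spans must cover [0, {n})")
        if self.utr5[1] != self.cds[0] or self.cds[1] != self.utr3[0]:
            raise ValueError(f"{self.gene_symbol}: spans must be contiguous")

    @classmethod
    def from_boundaries(cls, gene_symbol: str, sequence: str, utr5_end: int, cds_end: int) -> "Transcript":
        """Build from the two internal boundaries (5'UTR end, CDS end)."""
        n = len(sequence)
        return cls(gene_symbol, sequence, (0, utr5_end), (utr5_end, cds_end), (cds_end, n))

    def region_spans(self) -> dict[str, tuple[int, int]]:
        return {"5UTR": self.utr5, "CDS": self.cds, "3UTR": self.utr3}


@dataclass(frozen=True)
class RG4ScanConfig:
    """Structural constraints and scoring parameters for the rG4 scan.

    Defaults are the canonical screen: G-tracts of >= 3 Gs, loops 1-7 nt,
    a 20-nt scoring window, and positivity at score >= 0.5.  ``min_tract_len``
    may be lowered to 2 for relaxed two-layer scanning.
    """

    min_tract_len: int = 3
    n_tracts: int = 4
    loop_min: int = 1
    loop_max: int = 7
    window: int = 20
    prob_threshold: float = 0.5

    def __post_init__(self) -> None:
        if self.min_tract_len < 2:
            raise ValueError("min_tract_len must be >= 2")
        if self.loop_min > self.loop_max or self.loop_min < 0:
            raise ValueError("need 0 <= loop_min <= loop_max")
        if self.window <= 0:
            raise ValueError("window must be positive")
        if not 0.0 <= self.prob_threshold <= 1.0:
            raise ValueError("prob_threshold must lie in [0, 1]")


@dataclass
class G4Motif:
    """One detected four-tract motif in transcript coordinates.

    ``layers`` is the number of stacked tetrad layers, taken as the shortest
    tract length in the motif; ``representative_loop`` is the median of the
    loop lengths (the single per-element loop value reported in summaries).
    """

    start: int
    end: int
    tract_lengths: list[int]
    loop_lengths: list[int]
    layers: int
    representative_loop: int
    score: float = float("nan")
    region: str | None = None


@dataclass
class RG4Profile:
    """Per-gene aggregate of retained (score >= threshold) motifs."""

    gene_symbol: str
    motifs: list[G4Motif]
    n_rg4: int
    region_counts: dict[str, int]
    positive: bool


def find_g_runs(sequence: str, min_len: int) -> list[tuple[int, int, int]]:
    """All maximal runs of G with length >= ``min_len`` as (start, end, length).

    Runs are maximal, hence non-overlapping and sorted by start.
    """
    if min_len < 1:
        raise ValueError("min_len must be >= 1")
    seq = normalize_sequence(sequence)
    if not seq:
        raise ValueError("empty sequence")
    runs: list[tuple[int, int, int]] = []
    i = 0
    n = len(seq)
    while i < n:
        if seq[i] == "G":
            j = i
            while j < n and seq[j] == "G":
                j += 1
            if j - i >= min_len:
                runs.append((i, j, j - i))
            i = j
        else:
            i += 1
    return runs


def assemble_motifs(
    g_runs: Sequence[tuple[int, int, int]],
    sequence: str,
    config: RG4ScanConfig = RG4ScanConfig(),
) -> list[G4Motif]:
    """Chain consecutive G-runs into four-tract motifs, leftmost-greedy.

    A motif chains ``n_tracts`` consecutive runs whose inter-run gaps (loops)
    all lie in [loop_min, loop_max].  Selection is leftmost-greedy and
    non-overlapping: scanning runs left to right, the first chainable window
    of runs is emitted and its runs are consumed, so a run participates in at
    most one motif.  Motifs are returned unscored and unregioned.
    """
    k = config.n_tracts
    motifs: list[G4Motif] = []
    i = 0
    while i + k <= len(g_runs):
        chain = g_runs[i : i + k]
        loops = [chain[t + 1][0] - chain[t][1] for t in range(k - 1)]
        if all(config.loop_min <= L <= config.loop_max for L in loops):
            tracts = [r[2] for r in chain]
            loops_sorted = sorted(loops)
            motifs.append(
                G4Motif(
                    start=chain[0][0],
                    end=chain[-1][1],
                    tract_lengths=tracts,
                    loop_lengths=loops,
                    layers=min(tracts),
                    representative_loop=loops_sorted[len(loops_sorted) // 2],
                )
            )
            i += k
        else:
            i += 1
    return motifs


def _window_bounds(start: int, end: int, window: int, seq_len: int) -> tuple[int, int]:
    """Extend [start, end) symmetrically to at least ``window`` nt, truncated."""
    span = end - start
    if span < window:
        extra = window - span
        start -= extra // 2
        end += extra - extra // 2
    return max(0, start), min(seq_len, end)


def score_motif(motif: G4Motif, sequence: str, config: RG4ScanConfig = RG4ScanConfig()) -> float:
    """Deterministic G4Hunter-style window score in [0, 1].

    Each base in a G-run of length L contributes +min(L, 4), each base in a
    C-run -min(L, 4), other bases 0.  Runs are decomposed within the evaluated
    window only, so the score never depends on bases outside it.  The window
    is the motif span extended symmetrically to at least ``config.window`` nt
    (truncated at sequence boundaries), and the score is the window mean
    divided by 4, clamped to [0, 1].
    """
    seq = normalize_sequence(sequence)
    if not 0 <= motif.start <= motif.end <= len(seq):
        raise ValueError(f"motif span ({motif.start}, {motif.end}) out of bounds")
    lo, hi = _window_bounds(motif.start, motif.end, config.window, len(seq))
    window = seq[lo:hi]
    total = 0
    i = 0
    while i < len(window):
        base = window[i]
        if base in "GC":
            j = i
            while j < len(window) and window[j] == base:
                j += 1
            value = min(j - i, 4)
            total += (value if base == "G" else -value) * (j - i)
            i = j
        else:
            i += 1
    mean = total / len(window)
    return min(max(mean / 4.0, 0.0), 1.0)


def annotate_region(motif: G4Motif, transcript: Transcript) -> str:
    """Region (5UTR / CDS / 3UTR) containing the majority of the motif span.

    Ties go to the more downstream region.
    """
    if not 0 <= motif.start <= motif.end <= len(transcript.sequence):
        raise ValueError(f"motif span ({motif.start}, {motif.end}) outside transcript")
    best_region, best_overlap = REGIONS[0], -1
    for region, (s, e) in transcript.region_spans().items():
        overlap = max(0, min(motif.end, e) - max(motif.start, s))
        if overlap >= best_overlap:  # >= : later (downstream) region wins ties
            best_region, best_overlap = region, overlap
    return best_region


def scan_transcript(transcript: Transcript, config: RG4ScanConfig = RG4ScanConfig()) -> list[G4Motif]:
    """Find, score and region-annotate every motif in one transcript (unfiltered)."""
    runs = find_g_runs(transcript.sequence, config.min_tract_len)
    motifs = assemble_motifs(runs, transcript.sequence, config)
    for m in motifs:
        m.score = score_motif(m, transcript.sequence, config)
        m.region = annotate_region(m, transcript)
    return motifs


def profile_genes(
    transcripts: Sequence[Transcript], config: RG4ScanConfig = RG4ScanConfig()
) -> list[RG4Profile]:
    """Per-gene rG4 profiles keeping only motifs with score >= prob_threshold."""
    seen: set[str] = set()
    profiles: list[RG4Profile] = []
    for tx in transcripts:
        if tx.gene_symbol in seen:
            raise ValueError(f"duplicate gene symbol {tx.gene_symbol!r}")
        seen.add(tx.gene_symbol)
        retained = [m for m in scan_transcript(tx, config) if m.score >= config.prob_threshold]
        counts = Counter(m.region for m in retained)
        profiles.append(
            RG4Profile(
                gene_symbol=tx.gene_symbol,
                motifs=retained,
                n_rg4=len(retained),
                region_counts={r: counts.get(r, 0) for r in REGIONS},
                positive=bool(retained),
            )
        )
    return profiles


@dataclass
class StructureSummary:
    """Cohort-level structural statistics over all retained motifs.

    Each table maps a category to (count, percentage); percentages are
    half-up rounded to 2 decimals and are absent (empty dict) when there are
    no motifs to summarise.
    """

    n_motifs: int
    n_positive_genes: int
    region_table: dict[str, tuple[int, float]] = field(default_factory=dict)
    gene_count_bins: dict[str, tuple[int, float]] = field(default_factory=dict)
    layer_table: dict[str, tuple[int, float]] = field(default_factory=dict)
    loop_table: dict[int, tuple[int, float]] = field(default_factory=dict)


def _with_percent(counts: Mapping, total: int) -> dict:
    return {k: (c, percent(c, total)) for k, c in counts.items()}


def summarize_structures(profiles: Sequence[RG4Profile]) -> StructureSummary:
    """Region, per-gene count-bin, tetrad-layer and loop-length tables.

    Layers are binned as 2 / 3 / 4 / >=5 and per-gene motif counts as
    1 / 2 / >=3, mirroring the conventional presentation of rG4 screens.
    """
    if not profiles:
        raise ValueError("profiles must be non-empty")
    motifs = [m for p in profiles for m in p.motifs]
    positive = [p for p in profiles if p.positive]
    summary = StructureSummary(n_motifs=len(motifs), n_positive_genes=len(positive))
    if not motifs:
        return summary

    region_counts = Counter(m.region for m in motifs)
    summary.region_table = _with_percent(
        {r: region_counts.get(r, 0) for r in REGIONS}, len(motifs)
    )

    bins = Counter("1" if p.n_rg4 == 1 else "2" if p.n_rg4 == 2 else ">=3" for p in positive)
    summary.gene_count_bins = _with_percent(
        {b: bins.get(b, 0) for b in ("1", "2", ">=3")}, len(positive)
    )

    layer_bins = Counter(str(m.layers) if m.layers <= 4 else ">=5" for m in motifs)
    summary.layer_table = _with_percent(
        {b: layer_bins.get(b, 0) for b in ("2", "3", "4", ">=5")}, len(motifs)
    )

    loop_counts = Counter(m.representative_loop for m in motifs)
    summary.loop_table = _with_percent(
        {L: loop_counts.get(L, 0) for L in sorted(loop_counts)}, len(motifs)
    )
    return summary


def positivity_stats(
    profiles: Sequence[RG4Profile], directions: Mapping[str, str]
) -> dict[str, float]:
    """Overall / up-regulated / down-regulated positivity rates as percentages.

    ``directions`` must label every profiled gene as 'up' or 'down'.
    """
    missing = [p.gene_symbol for p in profiles if p.gene_symbol not in directions]
    if missing:
        raise ValueError(f"missing direction for genes: {missing[:5]}")
    out: dict[str, float] = {}
    strata = {
        "overall_rate": profiles,
        "up_rate": [p for p in profiles if directions[p.gene_symbol] == "up"],
        "down_rate": [p for p in profiles if directions[p.gene_symbol] == "down"],
    }
    for name, group in strata.items():
        if group:
            out[name] = percent(sum(p.positive for p in group), len(group))
    return out


def threshold_sweep(
    transcripts: Sequence[Transcript],
    config: RG4ScanConfig = RG4ScanConfig(),
    thresholds: Iterable[float] = (0.4, 0.5, 0.6),
    core_genes: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Positivity sensitivity analysis across score thresholds.

    For each threshold: number of positive genes, positivity rate,
    intersection with the default-threshold positive set (rate relative to
    the default positive count), and retention of a designated core gene set.
    Positives are nested, so n_positive is non-increasing in threshold.
    """
    thresholds = sorted(set(thresholds) | {config.prob_threshold})
    if any(not 0.0 <= t <= 1.0 for t in thresholds):
        raise ValueError("thresholds must lie in [0, 1]")
    scans = {tx.gene_symbol: scan_transcript(tx, config) for tx in transcripts}
    best = {g: max((m.score for m in ms), default=-1.0) for g, ms in scans.items()}

    def positives(theta: float) -> set[str]:
        return {g for g, s in best.items() if s >= theta}

    default_pos = positives(config.prob_threshold)
    core = {g.strip().upper() for g in core_genes} if core_genes is not None else None
    rows = []
    for theta in thresholds:
        pos = positives(theta)
        row = {
            "threshold": theta,
            "n_genes": len(transcripts),
            "n_positive": len(pos),
            "rate": percent(len(pos), len(transcripts)) if transcripts else float("nan"),
            "n_intersection_default": len(pos & default_pos),
            "intersection_rate": (
                percent(len(pos & default_pos), len(default_pos)) if default_pos else float("nan")
            ),
        }
        if core is not None:
            kept = {g for g in pos if g.upper() in core}
            row["core_retained"] = len(kept)
            row["core_retention_rate"] = percent(len(kept), len(core)) if core else float("nan")
        rows.append(row)
    return pd.DataFrame(rows)
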