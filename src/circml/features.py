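"""Sequence-derived feature extraction and feature-vector assembly.

Two vectors are assembled here:

* the circRNA-vs-lncRNA vector — 70 sequence-composition features, 101
  graph features taken from an externally computed matrix via a ranking
  list, 12 conservation-score summaries and 5 ATOS features (ALU count,
  tandem-repeat frequency, longest ORF, ORF propensity, SNP density) for
  188 features in baseline mode; full mode appends A-to-I count, A-to-I
  density and an IRES score for 191;
* the regulatory-interaction vector — 182 features in four groups:
  sequence-based (70 composition + tandem-repeat = 71), graph (101),
  genome context (7) and regulatory information (3).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .seqio import FeatureTable, IntervalTrack, ScoreTrack, TranscriptRecord

logger = logging.getLogger(__name__)

TRINUCLEOTIDES: list[str] = ["".join(p) for p in itertools.product("ACGT", repeat=3)]
_TRI_INDEX = {t: i for i, t in enumerate(TRINUCLEOTIDES)}

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})

#: the 12 conservation summaries emitted by default; the first seven are the
#: canonically described ones, the rest pad the block to the conventional
#: 12-statistic width (each can be switched off via ConservationConfig).
CONSERVATION_STATS: tuple[str, ...] = (
    "cons_mean",
    "cons_max",
    "cons_var",
    "cons_frac_gt_03",
    "cons_frac_gt_06",
    "cons_frac_gt_09",
    "cons_frac_lt_09",
    "cons_min",
    "cons_median",
    "cons_std",
    "cons_frac_gt_01",
    "cons_frac_gt_05",
)


@dataclass
class ConservationConfig:
    stats: tuple[str, ...] = CONSERVATION_STATS

    def __post_init__(self) -> None:
        unknown = set(self.stats) - set(CONSERVATION_STATS)
        if unknown:
            raise ValueError(f"unknown conservation statistics: {sorted(unknown)}")


@dataclass
class TandemRepeatConfig:
    """Built-in tandem-repeat detector: maximal runs of a 1-6 nt unit with at
    least two full copies and a minimum run length, counted per nucleotide."""

    max_unit: int = 6
    min_copies: int = 2
    min_run: int = 6


def trinucleotide_frequencies(seq: str) -> np.ndarray:
    """Overlapping 3-mer frequencies in lexicographic order AAA..TTT.

    Each count is divided by the number of windows (len - 2); sequences
    shorter than 3 nt yield the all-zero vector.
    """
    out = np.zeros(64, dtype=float)
    n = len(seq)
    if n < 3:
        return out
    for i in range(n - 2):
        out[_TRI_INDEX[seq[i : i + 3]]] += 1.0
    out /= n - 2
    return out


def motif_frequency(seq: str, motif: str) -> float:
    """Overlapping occurrences of ``motif`` divided by the window count."""
    m = len(motif)
    windows = len(seq) - m + 1
    if windows <= 0:
        return 0.0
    count = sum(1 for i in range(windows) if seq[i : i + m] == motif)
    return count / windows


def gc_content(seq: str) -> float:
    return (seq.count("G") + seq.count("C")) / len(seq)


def composition_block(seq: str) -> dict[str, float]:
    """The 70 sequence-composition features: 64 trinucleotide frequencies,
    length, GC content and the AG / GT / AGGT / GTAG motif frequencies."""
    tri = trinucleotide_frequencies(seq)
    block: dict[str, float] = {f"tri_{t}": tri[i] for i, t in enumerate(TRINUCLEOTIDES)}
    block["length"] = float(len(seq))
    block["gc"] = gc_content(seq)
    for motif in ("AG", "GT", "AGGT", "GTAG"):
        block[f"freq_{motif}"] = motif_frequency(seq, motif)
    return block


def conservation_block(
    rec: TranscriptRecord,
    track: ScoreTrack,
    config: ConservationConfig | None = None,
) -> dict[str, float]:
    """Summary statistics of the per-base conservation scores over the
    transcript span.  Records without coordinates get an all-zero block."""
    config = config or ConservationConfig()
    if not rec.has_coordinates:
        logger.warning("record %r has no coordinates; conservation block set to 0", rec.id)
        return {s: 0.0 for s in config.stats}
    if track.covered_bases(rec.chrom, rec.start0, rec.end0) == 0:  # type: ignore[arg-type]
        logger.debug("record %r has no conservation coverage; block set to 0", rec.id)
        return {s: 0.0 for s in config.stats}
    scores = track.per_base(rec.chrom, rec.start0, rec.end0)  # type: ignore[arg-type]
    values = {
        "cons_mean": float(np.mean(scores)),
        "cons_max": float(np.max(scores)),
        "cons_var": float(np.var(scores)),
        "cons_frac_gt_03": float(np.mean(scores > 0.3)),
        "cons_frac_gt_06": float(np.mean(scores > 0.6)),
        "cons_frac_gt_09": float(np.mean(scores > 0.9)),
        "cons_frac_lt_09": float(np.mean(scores < 0.9)),
        "cons_min": float(np.min(scores)),
        "cons_median": float(np.median(scores)),
        "cons_std": float(np.std(scores)),
        "cons_frac_gt_01": float(np.mean(scores > 0.1)),
        "cons_frac_gt_05": float(np.mean(scores > 0.5)),
    }
    return {s: values[s] for s in config.stats}


def overlap_count(rec: TranscriptRecord, track: IntervalTrack) -> int:
    """Number of track intervals intersecting the transcript span by >=1 base."""
    if not rec.has_coordinates:
        logger.warning("record %r has no coordinates; overlap count is 0", rec.id)
        return 0
    return track.overlap_count(rec.chrom, rec.start0, rec.end0)  # type: ignore[arg-type]


def snp_density(rec: TranscriptRecord, snp_track: IntervalTrack) -> float:
    """SNP sites overlapping the transcript, per nucleotide of its sequence."""
    return overlap_count(rec, snp_track) / len(rec.sequence)


def atoi_features(rec: TranscriptRecord, atoi_track: IntervalTrack) -> tuple[int, float]:
    """A-to-I editing-site count and density (count / sequence length)."""
    count = overlap_count(rec, atoi_track)
    return count, count / len(rec.sequence)


def longest_orf(seq: str) -> tuple[int, float]:
    """Longest open reading frame over the three forward frames.

    An ORF runs from an ATG to the first in-frame stop codon, stop included.
    Returns (length in nt, length / sequence length); (0, 0.0) when no
    complete ORF exists.
    """
    n = len(seq)
    best = 0
    for frame in range(3):
        open_start = -1  # earliest ATG since the last stop in this frame
        for i in range(frame, n - 2, 3):
            codon = seq[i : i + 3]
            if codon == "ATG" and open_start < 0:
                open_start = i
            elif codon in STOP_CODONS:
                if open_start >= 0:
                    best = max(best, i + 3 - open_start)
                open_start = -1
    return best, best / n if n else 0.0


def _is_primitive_period(run: str, unit: int) -> bool:
    """True when ``unit`` is the smallest period of ``run``."""
    for v in range(1, unit):
        if all(run[k] == run[k + v] for k in range(len(run) - v)):
            return False
    return True


def tandem_repeat_runs(seq: str, config: TandemRepeatConfig | None = None) -> list[tuple[int, int]]:
    """Maximal tandem runs (start, end spans, 0-based half-open) under the
    built-in detector: unit size 1..max_unit, >= min_copies full copies,
    run length >= min_run nt; each span reported once at its primitive period."""
    config = config or TandemRepeatConfig()
    n = len(seq)
    spans: set[tuple[int, int]] = set()
    for unit in range(1, config.max_unit + 1):
        i = 0
        while i + unit < n:
            if seq[i] != seq[i + unit]:
                i += 1
                continue
            # extend the period-`unit` match maximally in both directions
            j = i + unit
            while j + 1 < n and seq[j + 1 - unit] == seq[j + 1]:
                j += 1
            start = i
            end = j + 1  # run spans [start, end) with period `unit`
            length = end - start
            if length >= max(config.min_run, config.min_copies * unit):
                if _is_primitive_period(seq[start:end], unit):
                    spans.add((start, end))
            i = end - unit + 1
    return sorted(spans)


def tandem_repeat_freq(
    seq: str,
    config: TandemRepeatConfig | None = None,
    external_count: float | None = None,
) -> float:
    """Tandem-repeat frequency: detected runs per nucleotide.

    When ``external_count`` is given (e.g. the region count reported by an
    external repeat finder) it replaces the built-in detector's run count.
    """
    if external_count is not None:
        return float(external_count) / len(seq)
    return len(tandem_repeat_runs(seq, config)) / len(seq)


def ires_score(rec_id: str, external_scores: Mapping[str, float] | None = None) -> float:
    """Externally supplied IRES propensity clipped to [0, 1]; 0.0 when absent."""
    if external_scores is None or rec_id not in external_scores:
        logger.debug("no IRES score for %r; using 0.0", rec_id)
        return 0.0
    raw = float(external_scores[rec_id])
    clipped = min(1.0, max(0.0, raw))
    if clipped != raw:
        logger.warning("IRES score %g for %r clipped to [0, 1]", raw, rec_id)
    return clipped


def graph_feature_select(matrix: FeatureTable, ranking: Sequence[str], k: int = 101) -> FeatureTable:
    """The top-``k`` columns of an externally computed graph-feature matrix,
    in ranking-list order (the conventional choice is the top 101)."""
    if k > len(ranking):
        raise ValueError(f"k={k} exceeds ranking length {len(ranking)}")
    chosen = list(ranking[:k])
    available = set(matrix.feature_names)
    unknown = [n for n in chosen if n not in available]
    if unknown:
        raise KeyError(f"ranking names absent from the graph matrix: {unknown}")
    out = matrix.select_features(chosen)
    out.group_of = {n: "graph" for n in chosen}
    return out


@dataclass
class TrackSet:
    """The annotation inputs consumed by vector assembly."""

    alu: IntervalTrack | None = None
    snp: IntervalTrack | None = None
    atoi: IntervalTrack | None = None
    conservation: ScoreTrack | None = None


_EMPTY_INTERVALS = IntervalTrack(name="empty")
_EMPTY_SCORES = ScoreTrack(name="empty")


def _track_or_empty(track, empty, what: str):
    if track is None:
        logger.warning("no %s track supplied; derived features will be 0", what)
        return empty
    return track


@dataclass
class MinMaxParams:
    """Per-feature (min, max) fitted on training rows for [0, 1] scaling."""

    feature_names: list[str]
    mins: np.ndarray
    maxs: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"feature": self.feature_names, "min": self.mins, "max": self.maxs})


def fit_normalization(table: FeatureTable, fit_rows: Sequence[int] | None = None) -> MinMaxParams:
    rows = np.arange(table.n_transcripts) if fit_rows is None else np.asarray(list(fit_rows))
    if rows.size == 0:
        raise ValueError("fit_rows must be non-empty")
    sub = table.values[rows, :]
    return MinMaxParams(
        feature_names=list(table.feature_names),
        mins=sub.min(axis=0),
        maxs=sub.max(axis=0),
    )


def apply_normalization(table: FeatureTable, params: MinMaxParams) -> FeatureTable:
    """x' = (x - min) / (max - min), clipped to [0, 1]; constant features map to 0."""
    if list(table.feature_names) != list(params.feature_names):
        raise ValueError("normalization parameters do not match the table's features")
    span = params.maxs - params.mins
    safe = np.where(span > 0, span, 1.0)
    scaled = (table.values - params.mins) / safe
    scaled[:, span == 0] = 0.0
    scaled = np.clip(scaled, 0.0, 1.0)
    return FeatureTable(
        transcript_ids=list(table.transcript_ids),
        feature_names=list(table.feature_names),
        values=scaled,
        group_of=dict(table.group_of),
        labels=None if table.labels is None else table.labels.copy(),
    )


def normalize(
    table: FeatureTable, fit_rows: Sequence[int] | None = None
) -> tuple[FeatureTable, MinMaxParams]:
    """Min-max normalize each feature to [0, 1], fitting on ``fit_rows`` only
    (all rows by default); the returned parameters are reusable on held-out
    rows, whose values are clipped to [0, 1]."""
    params = fit_normalization(table, fit_rows)
    return apply_normalization(table, params), params


def _assemble(
    blocks: list[tuple[str, dict[str, float]]],
) -> tuple[list[str], list[float], dict[str, str]]:
    names: list[str] = []
    row: list[float] = []
    group_of: dict[str, str] = {}
    for tag, block in blocks:
        for name, value in block.items():
            names.append(name)
            row.append(float(value))
            group_of[name] = tag
    return names, row, group_of


def assemble_circlgb(
    records: Sequence[TranscriptRecord],
    tracks: TrackSet,
    graph_matrix: FeatureTable | None = None,
    graph_ranking: Sequence[str] | None = None,
    mode: str = "full",
    labels: np.ndarray | None = None,
    ires_scores: Mapping[str, float] | None = None,
    tandem_counts: Mapping[str, float] | None = None,
    conservation_config: ConservationConfig | None = None,
    tandem_config: TandemRepeatConfig | None = None,
    do_normalize: bool = True,
) -> FeatureTable:
    """Assemble the circRNA-identification feature table.

    ``mode='baseline'`` emits 188 features (70 composition + 101 graph + 12
    conservation + 5 ATOS); ``mode='full'`` appends A-to-I count, A-to-I
    density and the IRES score for 191.  Each feature is min-max scaled to
    [0, 1] over the assembled rows unless ``do_normalize`` is False.
    """
    if mode not in ("baseline", "full"):
        raise ValueError(f"mode must be 'baseline' or 'full', got {mode!r}")
    if graph_matrix is None:
        raise ValueError("a graph-feature matrix is required (101 graph columns)")
    if graph_ranking is None:
        raise ValueError("a graph-feature ranking list is required")
    graph = graph_feature_select(graph_matrix, graph_ranking, k=101)
    graph_rows = {tid: i for i, tid in enumerate(graph.transcript_ids)}

    alu = _track_or_empty(tracks.alu, _EMPTY_INTERVALS, "ALU")
    snp = _track_or_empty(tracks.snp, _EMPTY_INTERVALS, "SNP")
    atoi = _track_or_empty(tracks.atoi, _EMPTY_INTERVALS, "A-to-I")
    cons = _track_or_empty(tracks.conservation, _EMPTY_SCORES, "conservation")

    all_names: list[str] | None = None
    group_of: dict[str, str] = {}
    matrix: list[list[float]] = []
    for rec in records:
        count, density = atoi_features(rec, atoi)
        blocks: list[tuple[str, dict[str, float]]] = [
            ("composition", composition_block(rec.sequence)),
            (
                "graph",
                {
                    n: (graph.values[graph_rows[rec.id], j] if rec.id in graph_rows else 0.0)
                    for j, n in enumerate(graph.feature_names)
                },
            ),
            ("conservation", conservation_block(rec, cons, conservation_config)),
            (
                "atos",
                {
                    "alu_count": float(overlap_count(rec, alu)),
                    "tandem_repeat_freq": tandem_repeat_freq(
                        rec.sequence,
                        tandem_config,
                        None if tandem_counts is None else tandem_counts.get(rec.id),
                    ),
                    "longest_orf": float(longest_orf(rec.sequence)[0]),
                    "orf_prop": longest_orf(rec.sequence)[1],
                    "snp_density": snp_density(rec, snp),
                },
            ),
        ]
        if mode == "full":
            blocks.append(
                (
                    "new",
                    {
                        "atoi_count": float(count),
                        "atoi_density": density,
                        "ires_score": ires_score(rec.id, ires_scores),
                    },
                )
            )
        names, row, grp = _assemble(blocks)
        if all_names is None:
            all_names, group_of = names, grp
        matrix.append(row)

    table = FeatureTable(
        transcript_ids=[r.id for r in records],
        feature_names=all_names or [],
        values=np.array(matrix, dtype=float),
        group_of=group_of,
        labels=labels,
    )
    if do_normalize:
        table, _ = normalize(table)
    return table


def assemble_circmrt(
    records: Sequence[TranscriptRecord],
    tracks: TrackSet,
    annotations: pd.DataFrame | None = None,
    graph_matrix: FeatureTable | None = None,
    graph_ranking: Sequence[str] | None = None,
    labels: np.ndarray | None = None,
    tandem_counts: Mapping[str, float] | None = None,
    tandem_config: TandemRepeatConfig | None = None,
    do_normalize: bool = True,
) -> FeatureTable:
    """Assemble the 182-feature regulatory-interaction table.

    Groups: sequence (70 composition + tandem-repeat = 71), graph (101),
    genome_context (conservation mean/sd, ALU count, SNP density, A-to-I
    count, back-splice junction flag, miRNA-binding flag = 7) and regulatory
    (TF, methylation, H3K27ac flags = 3).  Missing per-transcript annotations
    encode as 0.
    """
    if graph_matrix is None or graph_ranking is None:
        raise ValueError("a graph-feature matrix and ranking list are required")
    graph = graph_feature_select(graph_matrix, graph_ranking, k=101)
    graph_rows = {tid: i for i, tid in enumerate(graph.transcript_ids)}

    alu = _track_or_empty(tracks.alu, _EMPTY_INTERVALS, "ALU")
    snp = _track_or_empty(tracks.snp, _EMPTY_INTERVALS, "SNP")
    atoi = _track_or_empty(tracks.atoi, _EMPTY_INTERVALS, "A-to-I")
    cons = _track_or_empty(tracks.conservation, _EMPTY_SCORES, "conservation")

    def flag(rec_id: str, col: str) -> float:
        if annotations is None or rec_id not in annotations.index or col not in annotations.columns:
            return 0.0
        return float(annotations.loc[rec_id, col])

    all_names: list[str] | None = None
    group_of: dict[str, str] = {}
    matrix: list[list[float]] = []
    for rec in records:
        seq_block = composition_block(rec.sequence)
        seq_block["tandem_repeat_freq"] = tandem_repeat_freq(
            rec.sequence,
            tandem_config,
            None if tandem_counts is None else tandem_counts.get(rec.id),
        )
        cons_stats = conservation_block(
            rec, cons, ConservationConfig(stats=("cons_mean", "cons_std"))
        )
        blocks: list[tuple[str, dict[str, float]]] = [
            ("sequence", seq_block),
            (
                "graph",
                {
                    n: (graph.values[graph_rows[rec.id], j] if rec.id in graph_rows else 0.0)
                    for j, n in enumerate(graph.feature_names)
                },
            ),
            (
                "genome_context",
                {
                    "cons_mean": cons_stats["cons_mean"],
                    "cons_sd": cons_stats["cons_std"],
                    "alu_count": float(overlap_count(rec, alu)),
                    "snp_density": snp_density(rec, snp),
                    "atoi_count": float(atoi_features(rec, atoi)[0]),
                    "junction": flag(rec.id, "junction"),
                    "mirna_binding": flag(rec.id, "mirna_binding"),
                },
            ),
            (
                "regulatory",
                {
                    "tf": flag(rec.id, "tf"),
                    "methylation": flag(rec.id, "methylation"),
                    "h3k27ac": flag(rec.id, "h3k27ac"),
                },
            ),
        ]
        names, row, grp = _assemble(blocks)
        if all_names is None:
            all_names, group_of = names, grp
        matrix.append(row)

    table = FeatureTable(
        transcript_ids=[r.id for r in records],
        feature_names=all_names or [],
        values=np.array(matrix, dtype=float),
        group_of=group_of,
        labels=labels,
    )
    if do_normalize:
        table, _ = normalize(table)
    return table
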