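"""Readers and writers for the external file formats used by the pipeline.

All genomic interval arithmetic inside the package uses the BED convention
(0-based, half-open).  Transcript coordinates carried in FASTA headers follow
the circBase convention (1-based, inclusive) and are converted exactly once,
here, at parse time.
"""

from __future__ import annotations

import logging
from bisect import bisect_left, bisect_right
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)

_CANONICAL = frozenset("ACGT")


@dataclass
class TranscriptRecord:
    """A transcript sequence, optionally with genomic coordinates.

    ``start``/``end`` are genomic, 1-based and inclusive (the convention used
    by circBase headers); :attr:`start0` / :attr:`end0` expose the 0-based
    half-open equivalents used for all overlap arithmetic.
    """

    id: str
    sequence: str
    chrom: str | None = None
    start: int | None = None
    end: int | None = None
    strand: str | None = None

    def __post_init__(self) -> None:
        if len(self.sequence) < 1:
            raise ValueError(f"record {self.id!r}: empty sequence")
        bad = set(self.sequence) - _CANONICAL
        if bad:
            raise ValueError(
                f"record {self.id!r}: non-canonical bases {sorted(bad)}; "
                "only A, C, G, T are accepted"
            )
        if self.has_coordinates and self.end < self.start:  # type: ignore[operator]
            raise ValueError(f"record {self.id!r}: end < start")

    @property
    def has_coordinates(self) -> bool:
        return self.chrom is not None and self.start is not None and self.end is not None

    @property
    def start0(self) -> int:
        """0-based half-open start (BED convention)."""
        if self.start is None:
            raise ValueError(f"record {self.id!r} has no coordinates")
        return self.start - 1

    @property
    def end0(self) -> int:
        """0-based half-open end (BED convention; equals the 1-based inclusive end)."""
        if self.end is None:
            raise ValueError(f"record {self.id!r} has no coordinates")
        return self.end

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class IntervalTrack:
    """A named set of genomic intervals in BED 0-based half-open convention."""

    name: str
    intervals: list[tuple[str, int, int]] = field(default_factory=list)
    _index: dict | None = field(default=None, repr=False, compare=False)

    def _build_index(self) -> dict:
        by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        tmp: dict[str, list[tuple[int, int]]] = {}
        for chrom, s, e in self.intervals:
            tmp.setdefault(chrom, []).append((s, e))
        for chrom, ivs in tmp.items():
            ivs.sort()
            starts = np.array([s for s, _ in ivs], dtype=np.int64)
            ends = np.array([e for _, e in ivs], dtype=np.int64)
            by_chrom[chrom] = (starts, ends)
        return by_chrom

    def overlap_count(self, chrom: str, start: int, end: int) -> int:
        """Number of intervals intersecting [start, end) by at least one base."""
        if self._index is None:
            self._index = self._build_index()
        entry = self._index.get(chrom)
        if entry is None:
            return 0
        starts, ends = entry
        return int(np.count_nonzero((starts < end) & (ends > start)))


@dataclass
class ScoreTrack:
    """Per-base scores in bedGraph convention; uncovered positions get a default."""

    name: str
    entries: list[tuple[str, int, int, float]] = field(default_factory=list)
    default: float = 0.0

    def __post_init__(self) -> None:
        self._by_chrom: dict[str, tuple[list[int], list[int], list[float]]] = {}
        tmp: dict[str, list[tuple[int, int, float]]] = {}
        for chrom, s, e, v in self.entries:
            if not np.isfinite(v):
                raise ValueError(f"score track {self.name!r}: non-finite value on {chrom}:{s}-{e}")
            tmp.setdefault(chrom, []).append((s, e, v))
        for chrom, ivs in tmp.items():
            ivs.sort()
            prev_end = -1
            for s, e, _ in ivs:
                if s < prev_end:
                    raise ValueError(
                        f"score track {self.name!r}: overlapping entries on {chrom} at {s}"
                    )
                prev_end = e
            self._by_chrom[chrom] = (
                [s for s, _, _ in ivs],
                [e for _, e, _ in ivs],
                [v for _, _, v in ivs],
            )

    def covered_bases(self, chrom: str, start: int, end: int) -> int:
        """Number of bases of [start, end) covered by any entry."""
        entry = self._by_chrom.get(chrom)
        if entry is None:
            return 0
        starts, ends, _ = entry
        lo = bisect_right(ends, start)
        hi = bisect_left(starts, end)
        return sum(
            max(0, min(ends[i], end) - max(starts[i], start)) for i in range(lo, hi)
        )

    def per_base(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Scores for every base of [start, end), 0-based half-open."""
        n = end - start
        out = np.full(n, self.default, dtype=float)
        entry = self._by_chrom.get(chrom)
        if entry is None:
            return out
        starts, ends, values = entry
        lo = bisect_right(ends, start)
        hi = bisect_left(starts, end)
        for i in range(lo, hi):
            s, e, v = starts[i], ends[i], values[i]
            a, b = max(s, start), min(e, end)
            if a < b:
                out[a - start : b - start] = v
        return out


@dataclass
class FeatureTable:
    """Feature matrix (transcripts x named features) with group tags and labels.

    The contract between feature extraction, selection and model training:
    feature names are unique, the matrix is dense with no missing values, and
    ``group_of`` tags every column with its feature-group name.
    """

    transcript_ids: list[str]
    feature_names: list[str]
    values: np.ndarray
    group_of: dict[str, str] = field(default_factory=dict)
    labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.transcript_ids), len(self.feature_names)):
            raise ValueError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.transcript_ids)} ids x {len(self.feature_names)} features"
            )
        if len(set(self.feature_names)) != len(self.feature_names):
            dupes = sorted({n for n in self.feature_names if self.feature_names.count(n) > 1})
            raise ValueError(f"duplicate feature names: {dupes}")
        if np.isnan(self.values).any():
            raise ValueError("feature matrix contains missing values")
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=int)
            if self.labels.shape != (len(self.transcript_ids),):
                raise ValueError("label vector length does not match number of transcripts")

    @property
    def n_transcripts(self) -> int:
        return len(self.transcript_ids)

    @property
    def n_features(self) -> int:
        return len(self.feature_names)

    def column(self, name: str) -> np.ndarray:
        return self.values[:, self.feature_names.index(name)]

    def select_features(self, names: Sequence[str]) -> "FeatureTable":
        """New table restricted to ``names``, in the given order."""
        missing = [n for n in names if n not in set(self.feature_names)]
        if missing:
            raise KeyError(f"unknown feature(s): {missing}")
        idx = [self.feature_names.index(n) for n in names]
        return FeatureTable(
            transcript_ids=list(self.transcript_ids),
            feature_names=list(names),
            values=self.values[:, idx].copy(),
            group_of={n: self.group_of[n] for n in names if n in self.group_of},
            labels=None if self.labels is None else self.labels.copy(),
        )

    def select_rows(self, rows: Sequence[int]) -> "FeatureTable":
        rows = list(rows)
        return FeatureTable(
            transcript_ids=[self.transcript_ids[i] for i in rows],
            feature_names=list(self.feature_names),
            values=self.values[rows, :].copy(),
            group_of=dict(self.group_of),
            labels=None if self.labels is None else self.labels[rows].copy(),
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, index=self.transcript_ids, columns=self.feature_names)
        df.index.name = "id"
        if self.labels is not None:
            df["label"] = self.labels
        return df


def _parse_header(description: str) -> tuple[str, str | None, int | None, int | None, str | None]:
    fields = description.split()
    rec_id = fields[0]
    if len(fields) >= 5:
        chrom, start_s, end_s, strand = fields[1:5]
        try:
            start, end = int(start_s), int(end_s)
        except ValueError:
            return rec_id, None, None, None, None
        if strand in ("+", "-"):
            return rec_id, chrom, start, end, strand
    return rec_id, None, None, None, None


def read_fasta(path: str | Path) -> list[TranscriptRecord]:
    """Read transcripts from FASTA.

    Headers carrying the five-field dialect ``>name chrom start end strand``
    (start/end 1-based inclusive) yield records with coordinates; other
    headers yield sequence-only records and a warning, since coordinate-
    dependent features will be skipped for them.  Sequences are upper-cased
    and U is mapped to T; any other non-ACGT character is rejected.
    """
    path = Path(path)
    records: list[TranscriptRecord] = []
    for seqrec in SeqIO.parse(str(path), "fasta"):
        rec_id, chrom, start, end, strand = _parse_header(seqrec.description)
        seq = str(seqrec.seq).upper().replace("U", "T")
        bad = set(seq) - _CANONICAL
        if bad:
            raise ValueError(
                f"record {rec_id!r}: forbidden character(s) {sorted(bad)} "
                "(only A, C, G, T/U are accepted)"
            )
        if chrom is None:
            logger.warning(
                "record %r has no 'name chrom start end strand' header; "
                "coordinate-dependent features will be 0",
                rec_id,
            )
        records.append(TranscriptRecord(rec_id, seq, chrom, start, end, strand))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    return records


def write_fasta(records: Iterable[TranscriptRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            if rec.has_coordinates:
                fh.write(f">{rec.id} {rec.chrom} {rec.start} {rec.end} {rec.strand}\n")
            else:
                fh.write(f">{rec.id}\n")
            fh.write(rec.sequence + "\n")


def read_interval_track(path: str | Path, name: str | None = None) -> IntervalTrack:
    """Read a BED3(+) file as an IntervalTrack (0-based half-open, verbatim)."""
    path = Path(path)
    intervals: list[tuple[str, int, int]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: expected >=3 tab-separated columns")
            chrom, start_s, end_s = parts[0], parts[1], parts[2]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from exc
            if start >= end:
                raise ValueError(f"{path}:{lineno}: start >= end ({start} >= {end})")
            intervals.append((chrom, start, end))
    return IntervalTrack(name=name or path.stem, intervals=intervals)


def write_interval_track(track: IntervalTrack, path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom, s, e in track.intervals:
            fh.write(f"{chrom}\t{s}\t{e}\n")


def read_score_track(path: str | Path, name: str | None = None, default: float = 0.0) -> ScoreTrack:
    """Read a 4-column bedGraph as a ScoreTrack (0-based half-open)."""
    path = Path(path)
    entries: list[tuple[str, int, int, float]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ValueError(f"{path}:{lineno}: expected 4 tab-separated columns")
            chrom, start_s, end_s, value_s = parts[:4]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from exc
            try:
                value = float(value_s)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-numeric score {value_s!r}") from exc
            if start >= end:
                raise ValueError(f"{path}:{lineno}: start >= end ({start} >= {end})")
            entries.append((chrom, start, end, value))
    return ScoreTrack(name=name or path.stem, entries=entries, default=default)


def write_score_track(track: ScoreTrack, path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom, s, e, v in track.entries:
            fh.write(f"{chrom}\t{s}\t{e}\t{v!r}\n")


def write_feature_table(table: FeatureTable, path: str | Path) -> None:
    """Write a FeatureTable as TSV with one ``#group:`` comment line per group."""
    groups: dict[str, list[str]] = {}
    for name in table.feature_names:
        tag = table.group_of.get(name, "ungrouped")
        groups.setdefault(tag, []).append(name)
    with open(path, "w") as fh:
        for tag, names in groups.items():
            fh.write(f"#group:{tag}=" + ",".join(names) + "\n")
        header = ["id"] + list(table.feature_names)
        if table.labels is not None:
            header.append("label")
        fh.write("\t".join(header) + "\n")
        for i, tid in enumerate(table.transcript_ids):
            row = [tid] + [repr(float(v)) for v in table.values[i]]
            if table.labels is not None:
                row.append(str(int(table.labels[i])))
            fh.write("\t".join(row) + "\n")


def read_feature_table(path: str | Path) -> FeatureTable:
    """Read a TSV feature table written by :func:`write_feature_table`.

    Round-trips names, ids and values to full precision.  The first column is
    the transcript id; an optional final ``label`` column carries class labels.
    """
    path = Path(path)
    group_of: dict[str, str] = {}
    header: list[str] | None = None
    rows: list[list[str]] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#group:"):
                body = line[len("#group:"):]
                tag, _, names = body.partition("=")
                for n in names.split(","):
                    if n:
                        group_of[n] = tag
                continue
            if line.startswith("#"):
                continue
            if header is None:
                header = line.split("\t")
            else:
                rows.append(line.split("\t"))
    if header is None:
        raise ValueError(f"{path}: empty feature table")
    has_label = header[-1] == "label"
    feature_names = header[1 : -1 if has_label else len(header)]
    if len(set(feature_names)) != len(feature_names):
        dupes = sorted({n for n in feature_names if feature_names.count(n) > 1})
        raise ValueError(f"{path}: duplicate feature column(s) {dupes}")
    ids = [r[0] for r in rows]
    values = np.array(
        [[float(v) for v in (r[1:-1] if has_label else r[1:])] for r in rows], dtype=float
    ).reshape(len(rows), len(feature_names))
    labels = np.array([int(r[-1]) for r in rows], dtype=int) if has_label else None
    return FeatureTable(ids, feature_names, values, group_of=group_of, labels=labels)


def read_ranking_list(path: str | Path) -> list[str]:
    """Read a plain-text feature ranking, one identifier per line, best first."""
    path = Path(path)
    names: list[str] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            name = line.strip()
            if not name:
                continue
            if name in seen:
                raise ValueError(f"{path}:{lineno}: duplicate identifier {name!r}")
            seen.add(name)
            names.append(name)
    if not names:
        raise ValueError(f"{path}: empty ranking list")
    return names


def write_ranking_list(names: Iterable[str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for n in names:
            fh.write(n + "\n")


def read_annotation_table(path: str | Path) -> pd.DataFrame:
    """Read the per-transcript regulatory annotation TSV.

    Expected columns: id, junction, mirna_binding, tf, methylation, h3k27ac
    (all flags binary).  Returns a DataFrame indexed by transcript id.
    """
    df = pd.read_csv(path, sep="\t", dtype={"id": str})
    if "id" not in df.columns:
        raise ValueError(f"{path}: annotation table must have an 'id' column")
    return df.set_index("id")


def read_score_map(path: str | Path) -> dict[str, float]:
    """Read a two-column TSV of (transcript id, score), e.g. external IRES scores."""
    df = pd.read_csv(path, sep="\t", header=None, names=["id", "score"], dtype={0: str})
    return dict(zip(df["id"], df["score"].astype(float)))
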