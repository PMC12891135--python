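"""Readers/writers for the formats the pipeline touches, and the core containers.

Coordinates are uniformly 0-based half-open throughout the package; BED input is
taken natively, SAM/BAM template coordinates are converted at the boundary.
Fragment strand is the strand of the template's 5'-most read (read 1).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple

import numpy as np
import pandas as pd

from .genome import Genome, GenomeSequence

logger = logging.getLogger(__name__)

FLOAT_FORMAT = "%.12g"  # 12 significant digits for lossless-enough TSV round trips


class FragmentFormatError(ValueError):
    """Raised for unparseable or inconsistent fragment input."""


class Fragment(NamedTuple):
    chrom: str
    start: int  # 0-based inclusive
    end: int  # exclusive
    strand: str  # '+' or '-'

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


@dataclass
class FragmentSet:
    """An ordered collection of aligned cfDNA fragments for one sample.

    Backed by a DataFrame with columns chrom/start/end/strand, sorted by
    (chrom, start); vectorised extractors work on the column arrays.
    """

    sample_id: str
    data: pd.DataFrame
    source: str = ""

    def __post_init__(self) -> None:
        required = ["chrom", "start", "end", "strand"]
        missing = [c for c in required if c not in self.data.columns]
        if missing:
            raise FragmentFormatError(f"fragment table missing columns: {missing}")
        df = self.data[required].copy()
        df["chrom"] = df["chrom"].astype(str)
        df["start"] = df["start"].astype(np.int64)
        df["end"] = df["end"].astype(np.int64)
        df["strand"] = df["strand"].astype(str)
        if (df["start"] < 0).any():
            raise FragmentFormatError("negative fragment start")
        if (df["end"] <= df["start"]).any():
            raise FragmentFormatError("fragment with end <= start")
        bad = ~df["strand"].isin(["+", "-"])
        if bad.any():
            raise FragmentFormatError(f"invalid strand {df.loc[bad, 'strand'].iloc[0]!r}")
        df = df.sort_values(["chrom", "start", "end", "strand"], kind="mergesort")
        self.data = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.data)

    def __iter__(self):
        for row in self.data.itertuples(index=False):
            yield Fragment(row.chrom, int(row.start), int(row.end), row.strand)

    @property
    def lengths(self) -> np.ndarray:
        return (self.data["end"] - self.data["start"]).to_numpy()

    @property
    def midpoints(self) -> np.ndarray:
        return ((self.data["start"] + self.data["end"]) // 2).to_numpy()

    def by_chrom(self):
        """Yield (chrom, starts, ends, strands) per chromosome, sorted."""
        for chrom, sub in self.data.groupby("chrom", sort=True):
            yield (
                chrom,
                sub["start"].to_numpy(),
                sub["end"].to_numpy(),
                sub["strand"].to_numpy(),
            )

    @classmethod
    def from_arrays(cls, sample_id, chrom, start, end, strand, source=""):
        df = pd.DataFrame(
            {"chrom": chrom, "start": start, "end": end, "strand": strand}
        )
        return cls(sample_id, df, source)


@dataclass
class IntervalTrack:
    """A set of named, categorised genomic intervals with point/overlap queries.

    0-based half-open, sorted per chromosome.  Point location resolves nested
    intervals to the smallest containing one.
    """

    data: pd.DataFrame
    _index: dict = field(default_factory=dict, repr=False, compare=False)

    COLUMNS = ["chrom", "start", "end", "name", "category", "strand"]

    def __post_init__(self) -> None:
        df = self.data.copy()
        for col, default in [("name", "."), ("category", ""), ("strand", "+")]:
            if col not in df.columns:
                df[col] = default
        df = df[self.COLUMNS]
        df["chrom"] = df["chrom"].astype(str)
        df["start"] = df["start"].astype(np.int64)
        df["end"] = df["end"].astype(np.int64)
        if len(df) and (df["end"] <= df["start"]).any():
            raise ValueError("interval with end <= start")
        df = df.sort_values(["chrom", "start", "end"], kind="mergesort").reset_index(drop=True)
        self.data = df

    def __len__(self) -> int:
        return len(self.data)

    @classmethod
    def empty(cls) -> "IntervalTrack":
        return cls(pd.DataFrame(columns=cls.COLUMNS))

    def _chrom_arrays(self, chrom: str):
        if chrom not in self._index:
            sub = self.data[self.data["chrom"] == chrom]
            self._index[chrom] = (
                sub["start"].to_numpy(),
                sub["end"].to_numpy(),
                sub.index.to_numpy(),
            )
        return self._index[chrom]

    def locate_points(self, chrom: str, pos: np.ndarray) -> np.ndarray:
        """Row index (into .data) of the smallest interval containing each
        position, or -1.  Vectorised for non-overlapping tracks; falls back to
        a scan where intervals nest."""
        pos = np.asarray(pos, dtype=np.int64)
        starts, ends, rows = self._chrom_arrays(chrom)
        out = np.full(len(pos), -1, dtype=np.int64)
        if len(starts) == 0:
            return out
        idx = np.searchsorted(starts, pos, side="right") - 1
        inside = (idx >= 0) & (pos < ends[np.clip(idx, 0, None)])
        out[inside] = rows[idx[inside]]
        overlapping = bool((starts[1:] < ends[:-1]).any())
        if overlapping:
            # resolve nesting: scan backwards over candidate containers,
            # keeping the smallest containing interval.
            sizes = ends - starts
            for i, p in enumerate(pos):
                best, best_size = -1, None
                j = min(int(np.searchsorted(starts, p, side="right")) - 1, len(starts) - 1)
                max_len = int(sizes.max())
                while j >= 0 and starts[j] > p - max_len:
                    if starts[j] <= p < ends[j]:
                        if best_size is None or sizes[j] < best_size:
                            best, best_size = rows[j], sizes[j]
                    j -= 1
                out[i] = best
        return out

    def overlap_bases(self, chrom: str, start: int, end: int) -> int:
        """Bases of [start, end) covered by the (merged) track."""
        starts, ends, _ = self._chrom_arrays(chrom)
        if len(starts) == 0:
            return 0
        total = 0
        cur_s = cur_e = None
        for s, e in zip(starts, ends):
            if cur_s is None:
                cur_s, cur_e = s, e
            elif s <= cur_e:
                cur_e = max(cur_e, e)
            else:
                total += max(0, min(cur_e, end) - max(cur_s, start))
                cur_s, cur_e = s, e
        if cur_s is not None:
            total += max(0, min(cur_e, end) - max(cur_s, start))
        return int(total)


@dataclass
class FeatureMatrix:
    """Samples x named features, with class labels and subgroup metadata.

    ``values`` is indexed by sample_id; ``labels`` uses 0 = benign,
    1 = malignant; ``metadata`` carries sex/age/stage when known.
    """

    values: pd.DataFrame
    labels: pd.Series | None = None
    metadata: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            dup = self.values.index[self.values.index.duplicated()][0]
            raise ValueError(f"duplicate sample_id {dup!r} in feature matrix")
        self.values.index.name = "sample_id"
        if self.labels is not None:
            self.labels = self.labels.reindex(self.values.index).astype(float)
            if self.labels.isna().any():
                missing = self.labels.index[self.labels.isna()][0]
                raise ValueError(f"sample {missing!r} has no label")
            self.labels = self.labels.astype(int)
        if self.metadata is not None:
            self.metadata = self.metadata.reindex(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def feature_names(self) -> list[str]:
        return list(self.values.columns)

    def subset(self, sample_ids) -> "FeatureMatrix":
        ids = list(sample_ids)
        return FeatureMatrix(
            self.values.loc[ids].copy(),
            self.labels.loc[ids].copy() if self.labels is not None else None,
            self.metadata.loc[ids].copy() if self.metadata is not None else None,
        )


# ---------------------------------------------------------------------------
# FASTA


def read_genome(path) -> Genome:
    """Read a (multi-record) FASTA into a :class:`Genome`."""
    from Bio import SeqIO

    records = [
        GenomeSequence(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")
    ]
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    return Genome(records)


def write_genome(genome: Genome, path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, chrom in genome.items():
            fh.write(f">{name}\n")
            seq = chrom.sequence
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# BED / intervals


def read_intervals(path, category_column: int | None = 6) -> IntervalTrack:
    """Read a BED-like table (>=3 cols; name/score/strand/category optional).

    ``category_column`` is the 0-based index of an extra category column; it is
    used when present in the file, otherwise category is left blank (and may be
    derived later from the name, e.g. via repeat-family classification).
    """
    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{ln}: BED line with < 3 columns")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            name = parts[3] if len(parts) > 3 else "."
            strand = parts[5] if len(parts) > 5 and parts[5] in "+-" else "+"
            category = ""
            if category_column is not None and len(parts) > category_column:
                category = parts[category_column]
            rows.append((chrom, start, end, name, category, strand))
    return IntervalTrack(
        pd.DataFrame(rows, columns=IntervalTrack.COLUMNS)
        if rows
        else pd.DataFrame(columns=IntervalTrack.COLUMNS)
    )


def write_intervals(track: IntervalTrack, path) -> None:
    """Write 6-column BED plus a 7th category column when any is set."""
    df = track.data
    with open(path, "w") as fh:
        has_cat = bool((df["category"].astype(str) != "").any()) if len(df) else False
        for row in df.itertuples(index=False):
            cols = [row.chrom, str(row.start), str(row.end), row.name, "0", row.strand]
            if has_cat:
                cols.append(str(row.category))
            fh.write("\t".join(map(str, cols)) + "\n")


# ---------------------------------------------------------------------------
# Fragments


def read_fragments(
    path,
    sample_id: str | None = None,
    min_mapq: int = 30,
    length_range: tuple[int, int] = (30, 700),
    dedupe: bool = True,
) -> FragmentSet:
    """Read fragments from a SAM/BAM (paired reads) or a fragment table (TSV).

    SAM path: properly paired primary alignments are paired by name; both mates
    must have MAPQ >= ``min_mapq``; template length must fall in
    ``length_range``; when ``dedupe`` duplicate-flagged reads are dropped and
    identical (chrom, start, end, strand) templates collapse to one.
    Discard counts are logged.
    """
    path = Path(path)
    if sample_id is None:
        sample_id = path.stem
    if path.suffix.lower() in {".sam", ".bam", ".cram"}:
        return _read_fragments_sam(path, sample_id, min_mapq, length_range, dedupe)
    return _read_fragment_table(path, sample_id, length_range, dedupe)


def _read_fragment_table(path, sample_id, length_range, dedupe) -> FragmentSet:
    with open(path) as fh:
        first = fh.readline()
    if not first:
        raise FragmentFormatError(f"{path}: empty fragment table")
    has_header = first.split("\t")[0].strip().lower() in {"chrom", "chr", "chromosome"}
    df = pd.read_csv(
        path,
        sep="\t",
        header=0 if has_header else None,
        names=None if has_header else ["chrom", "start", "end", "strand"],
        dtype={0: str},
    )
    df.columns = [str(c).lower() for c in df.columns]
    if "strand" not in df.columns:
        raise FragmentFormatError(f"{path}: fragment table requires a strand column")
    n0 = len(df)
    length = df["end"].astype(int) - df["start"].astype(int)
    keep = (length >= length_range[0]) & (length <= length_range[1])
    df = df[keep]
    if dedupe:
        df = df.drop_duplicates(subset=["chrom", "start", "end", "strand"])
    logger.info(
        "read_fragments(%s): kept %d/%d (length filter %d, duplicates %d)",
        path,
        len(df),
        n0,
        int((~keep).sum()),
        n0 - int((~keep).sum()) - len(df),
    )
    return FragmentSet(sample_id, df, source=str(path))


def _read_fragments_sam(path, sample_id, min_mapq, length_range, dedupe) -> FragmentSet:
    import pysam

    mode = "rb" if path.suffix.lower() == ".bam" else "r"
    pending: dict[str, object] = {}
    frags: list[tuple[str, int, int, str]] = []
    n_records = n_filtered = n_dup_flag = 0
    with pysam.AlignmentFile(str(path), mode, check_sq=False) as fh:
        for read in fh:
            n_records += 1
            if read.is_secondary or read.is_supplementary or read.is_unmapped:
                n_filtered += 1
                continue
            if dedupe and read.is_duplicate:
                n_dup_flag += 1
                continue
            if not read.is_paired or not read.is_proper_pair:
                n_filtered += 1
                continue
            mate = pending.pop(read.query_name, None)
            if mate is None:
                pending[read.query_name] = read
                continue
            r1 = read if read.is_read1 else mate
            r2 = mate if read.is_read1 else read
            if r1.reference_name != r2.reference_name:
                n_filtered += 1
                continue
            if r1.mapping_quality < min_mapq or r2.mapping_quality < min_mapq:
                n_filtered += 1
                continue
            start = min(r1.reference_start, r2.reference_start)
            end = max(r1.reference_end, r2.reference_end)
            if end <= start:
                raise FragmentFormatError(
                    f"{path}: degenerate template for read {read.query_name!r}"
                )
            if not (length_range[0] <= end - start <= length_range[1]):
                n_filtered += 1
                continue
            strand = "-" if r1.is_reverse else "+"
            frags.append((r1.reference_name, start, end, strand))
    if pending:
        n_filtered += len(pending)
        logger.info("read_fragments(%s): %d unpaired reads ignored", path, len(pending))
    if dedupe:
        before = len(frags)
        frags = sorted(set(frags))
        n_dup_flag += before - len(frags)
    logger.info(
        "read_fragments(%s): %d records -> %d fragments (%d filtered, %d duplicates)",
        path,
        n_records,
        len(frags),
        n_filtered,
        n_dup_flag,
    )
    df = pd.DataFrame(frags, columns=["chrom", "start", "end", "strand"])
    return FragmentSet(sample_id, df, source=str(path))


def write_fragments(fragments: FragmentSet, path) -> None:
    """Write the fragment table (chrom, start, end, strand) as TSV."""
    fragments.data.to_csv(path, sep="\t", index=False)


def write_fragments_sam(fragments: FragmentSet, genome: Genome, path, read_length: int = 50) -> None:
    """Write a minimal coordinate-sorted SAM realisation of the fragments.

    Each fragment becomes one proper FR read pair whose template spans exactly
    [start, end); a '+' template has read 1 forward-leftmost, a '-' template
    has read 1 reverse-rightmost.
    """
    import pysam

    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": name, "LN": chrom.length} for name, chrom in genome.items()],
    }
    refs = {name: i for i, name in enumerate(genome)}
    records = []
    for i, frag in enumerate(fragments):
        L = frag.length
        rlen = min(read_length, L)
        tid = refs[frag.chrom]
        left_seq = genome[frag.chrom].sequence[frag.start : frag.start + rlen]
        right_seq = genome[frag.chrom].sequence[frag.end - rlen : frag.end]
        for is_read1 in (True, False):
            a = pysam.AlignedSegment()
            a.query_name = f"{fragments.sample_id}:{i}"
            a.reference_id = tid
            a.cigarstring = f"{rlen}M"
            a.mapping_quality = 60
            flag = 0x1 | 0x2 | (0x40 if is_read1 else 0x80)
            # leftmost mate is always forward (FR); template strand decides
            # which mate sits left.
            left_is_read1 = frag.strand == "+"
            at_left = is_read1 == left_is_read1
            if at_left:
                a.reference_start = frag.start
                a.template_length = L
                a.query_sequence = left_seq
                flag |= 0x20  # mate reverse
            else:
                a.reference_start = frag.end - rlen
                a.template_length = -L
                a.query_sequence = right_seq
                flag |= 0x10  # this read reverse
            a.flag = flag
            a.next_reference_id = tid
            a.next_reference_start = frag.start if not at_left else frag.end - rlen
            records.append(a)
    records.sort(key=lambda a: (a.reference_id, a.reference_start, a.query_name))
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for a in records:
            out.write(a)


# ---------------------------------------------------------------------------
# Feature matrix / metadata TSV

_META_COLS = ["label", "sex", "age", "stage"]


def write_feature_matrix(matrix: FeatureMatrix, path) -> None:
    """TSV with sample_id, label/metadata columns, then features (12 sig digits)."""
    out = matrix.values.copy()
    lead = []
    if matrix.labels is not None:
        out.insert(0, "label", matrix.labels)
        lead.append("label")
    if matrix.metadata is not None:
        for i, col in enumerate([c for c in _META_COLS[1:] if c in matrix.metadata.columns]):
            out.insert(len(lead) + i, col, matrix.metadata[col])
    out.to_csv(path, sep="\t", float_format=FLOAT_FORMAT, index=True)


def read_feature_matrix(path) -> FeatureMatrix:
    df = pd.read_csv(path, sep="\t", index_col="sample_id")
    if df.index.duplicated().any():
        raise ValueError(f"{path}: duplicate sample_id")
    labels = None
    meta_cols = [c for c in _META_COLS if c in df.columns]
    metadata = df[ [c for c in meta_cols if c != "label"] ].copy() if meta_cols else None
    if "label" in df.columns:
        labels = df["label"].astype(int)
    values = df.drop(columns=meta_cols)
    return FeatureMatrix(values, labels, metadata)


def read_metadata(path) -> pd.DataFrame:
    """Sample metadata TSV: sample_id, label, sex, age, stage."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "stage": str})
    df = df.set_index("sample_id")
    if df.index.duplicated().any():
        raise ValueError(f"{path}: duplicate sample_id in metadata")
    return df


def write_metadata(metadata: pd.DataFrame, path) -> None:
    metadata.to_csv(path, sep="\t", index=True, index_label="sample_id")
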