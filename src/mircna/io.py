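"""Readers, writers and shared genomic coordinate conventions.

All genomic intervals are stored 0-based half-open internally.  BED input is
taken as-is; GFF3 and 1-based inclusive coordinates (the convention used by
miRBase-style locus tables) are converted on read.  Chromosome names are
normalized by stripping an optional ``chr`` prefix, so ``chr1`` and ``1``
address the same chromosome and a cytoband key looks like ``1q32.2``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

logger = logging.getLogger(__name__)

RAW_COUNTS = "raw_counts"
NORMALIZED_LOG2 = "normalized_log2"

#: copy-number gain/loss log2-ratio thresholds (test/reference orientation)
GAIN_THRESHOLD = 0.25
LOSS_THRESHOLD = -0.25
#: "more than 3 probes" aberration filter
MIN_PROBES = 4

STAGES = {"I", "II", "III"}
GRADES = {1, 2, 3}
BINARY = {"pos", "neg"}


class FormatError(ValueError):
    """Malformed input file (parse failure, duplicate ids, bad cell)."""


class ValidationError(ValueError):
    """Well-formed input violating a domain invariant."""


class LabelingError(ValueError):
    """Sample present in the data but missing from the group map."""


# ---------------------------------------------------------------------------
# coordinate conventions
# ---------------------------------------------------------------------------

def normalize_chrom(chrom: str) -> str:
    """Strip an optional ``chr`` prefix; ``chrX`` -> ``X``."""
    chrom = str(chrom).strip()
    if not chrom:
        raise ValidationError("empty chromosome name")
    return chrom[3:] if chrom.lower().startswith("chr") else chrom


def one_based_to_half_open(start: int, stop: int) -> tuple[int, int]:
    """Convert a 1-based inclusive interval to 0-based half-open."""
    if start > stop:
        raise ValidationError(f"1-based interval has start > stop: {start} > {stop}")
    return start - 1, stop


def half_open_to_one_based(start: int, stop: int) -> tuple[int, int]:
    """Inverse of :func:`one_based_to_half_open`."""
    if start >= stop:
        raise ValidationError(f"half-open interval is empty: [{start}, {stop})")
    return start + 1, stop


def overlaps(start_a: int, stop_a: int, start_b: int, stop_b: int) -> bool:
    """Nonempty intersection of two half-open intervals."""
    return start_a < stop_b and start_b < stop_a


# ---------------------------------------------------------------------------
# expression matrix
# ---------------------------------------------------------------------------

@dataclass
class ExpressionMatrix:
    """miRNA x sample abundance matrix with per-sample group labels.

    ``values`` is indexed by miRNA id with one column per sample; ``groups``
    maps each sample id to its group label (e.g. the two patient cohorts being
    compared).  ``scale`` records whether the body holds raw counts or
    normalized log2 abundances.
    """

    values: pd.DataFrame
    groups: pd.Series
    scale: str = RAW_COUNTS

    def __post_init__(self) -> None:
        if not isinstance(self.groups, pd.Series):
            self.groups = pd.Series(dict(self.groups))
        self.groups = self.groups.astype(str)
        idx = self.values.index
        cols = self.values.columns
        if idx.duplicated().any():
            dupes = idx[idx.duplicated()].unique().tolist()
            raise FormatError(f"duplicate miRNA ids: {dupes}")
        if cols.duplicated().any():
            dupes = cols[cols.duplicated()].unique().tolist()
            raise FormatError(f"duplicate sample ids: {dupes}")
        missing = [s for s in cols if s not in self.groups.index]
        if missing:
            raise LabelingError(f"samples missing from group map: {missing}")
        self.groups = self.groups.loc[cols]
        body = self.values.to_numpy()
        if not np.issubdtype(body.dtype, np.number):
            raise FormatError("expression matrix body must be numeric")
        if self.scale == RAW_COUNTS and (body < 0).any():
            bad = idx[np.where(body < 0)[0][0]]
            raise ValidationError(f"negative raw count for miRNA {bad!r}")
        if self.scale not in (RAW_COUNTS, NORMALIZED_LOG2):
            raise ValidationError(f"unknown scale {self.scale!r}")

    @property
    def mirna_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def group_names(self) -> list[str]:
        return sorted(self.groups.unique())

    def samples_of(self, group: str) -> list[str]:
        return list(self.groups.index[self.groups == group])


def read_expression_matrix(path: str | Path,
                           group_map: Mapping[str, str]) -> ExpressionMatrix:
    """Read a tab-separated counts table (first column miRNA id, header
    row sample ids) and attach group labels."""
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
    samples = header[1:]
    seen: set[str] = set()
    for s in samples:
        if s in seen:
            raise FormatError(f"{path.name}: duplicated sample header {s!r}")
        seen.add(s)
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.columns = samples
    for col in df.columns:
        numeric = pd.to_numeric(df[col], errors="coerce")
        bad = numeric.isna() & df[col].notna()
        if bad.any():
            row = df.index[bad.argmax()]
            raise FormatError(
                f"{path.name}: non-numeric cell at miRNA {row!r}, sample {col!r}")
        df[col] = numeric
    if df.isna().any().any():
        raise FormatError(f"{path.name}: empty cell in matrix body")
    return ExpressionMatrix(values=df, groups=pd.Series(dict(group_map)),
                            scale=RAW_COUNTS)


def write_expression_matrix(mat: ExpressionMatrix, path: str | Path) -> None:
    out = mat.values.copy()
    out.index.name = "mirna"
    out.to_csv(path, sep="\t", float_format="%.12g")


def read_group_map(path: str | Path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise FormatError(f"{Path(path).name}: expected columns sample, group")
    return dict(zip(df.iloc[:, 0], df.iloc[:, 1]))


def write_group_map(groups: Mapping[str, str], path: str | Path) -> None:
    pd.DataFrame({"sample": list(groups.keys()),
                  "group": list(groups.values())}).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# genomic loci
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Locus:
    """A named genomic interval (0-based half-open, chr prefix stripped)."""

    id: str
    chrom: str
    start: int
    stop: int
    strand: str = "."

    def __post_init__(self) -> None:
        object.__setattr__(self, "chrom", normalize_chrom(self.chrom))
        if self.start >= self.stop:
            raise ValidationError(
                f"locus {self.id!r}: empty interval [{self.start}, {self.stop})")
        if self.strand not in {"+", "-", "."}:
            raise ValidationError(f"locus {self.id!r}: bad strand {self.strand!r}")

    @classmethod
    def from_one_based(cls, id: str, chrom: str, start: int, stop: int,
                       strand: str = ".") -> "Locus":
        s, e = one_based_to_half_open(start, stop)
        return cls(id=id, chrom=chrom, start=s, stop=e, strand=strand)

    @property
    def mirna_id(self) -> str:  # alias in miRNA contexts
        return self.id


def read_loci_bed(path: str | Path) -> list[Locus]:
    """BED (0-based half-open) with the name field carrying the locus id."""
    rows = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    if rows.shape[1] < 4:
        raise FormatError(f"{Path(path).name}: BED needs >= 4 columns")
    loci = []
    for _, r in rows.iterrows():
        strand = r[5] if rows.shape[1] >= 6 and r[5] in {"+", "-"} else "."
        loci.append(Locus(id=r[3], chrom=r[0], start=int(r[1]), stop=int(r[2]),
                          strand=strand))
    return loci


def write_loci_bed(loci: Iterable[Locus], path: str | Path) -> None:
    with open(path, "w") as fh:
        for l in loci:
            fh.write(f"{l.chrom}\t{l.start}\t{l.stop}\t{l.id}\t0\t{l.strand}\n")


def read_loci_gff3(path: str | Path, id_attribute: str = "Name") -> list[Locus]:
    """GFF3 (1-based inclusive) miRNA loci; the ``Name=`` attribute is the id."""
    from gffutils.feature import feature_from_line

    loci = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            try:
                feat = feature_from_line(line)
            except Exception as exc:  # noqa: BLE001 - rewrap with location
                raise FormatError(f"{Path(path).name}:{lineno}: {exc}") from exc
            names = feat.attributes.get(id_attribute, [])
            if not names:
                raise FormatError(
                    f"{Path(path).name}:{lineno}: missing {id_attribute}= attribute")
            loci.append(Locus.from_one_based(
                id=names[0], chrom=feat.seqid, start=feat.start, stop=feat.end,
                strand=feat.strand if feat.strand in {"+", "-"} else "."))
    return loci


# ---------------------------------------------------------------------------
# cytobands
# ---------------------------------------------------------------------------

class CytobandMap:
    """Cytogenetic band intervals keyed like ``1q32.2``.

    Within each chromosome bands must be sorted and non-overlapping; the
    half-open convention means a position on a shared boundary belongs to the
    band on the right.
    """

    def __init__(self, records: pd.DataFrame):
        req = {"chrom", "start", "stop", "band"}
        if not req.issubset(records.columns):
            raise FormatError(f"cytoband table needs columns {sorted(req)}")
        df = records.copy()
        df["chrom"] = df["chrom"].map(normalize_chrom)
        df["start"] = df["start"].astype(int)
        df["stop"] = df["stop"].astype(int)
        if "stain" not in df.columns:
            df["stain"] = ""
        df["key"] = df["chrom"] + df["band"].astype(str)
        bad = df[df["start"] >= df["stop"]]
        if len(bad):
            rec = bad.iloc[0]
            raise ValidationError(
                f"band {rec['key']}: chromEnd <= chromStart "
                f"({rec['stop']} <= {rec['start']})")
        df = df.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)
        for chrom, grp in df.groupby("chrom"):
            starts = grp["start"].to_numpy()
            stops = grp["stop"].to_numpy()
            clash = np.nonzero(starts[1:] < stops[:-1])[0]
            if clash.size:
                i = clash[0]
                raise ValidationError(
                    f"overlapping bands on chromosome {chrom}: "
                    f"{grp['key'].iloc[i]} and {grp['key'].iloc[i + 1]}")
        if df["key"].duplicated().any():
            dupe = df["key"][df["key"].duplicated()].iloc[0]
            raise ValidationError(f"duplicate band key {dupe}")
        self.records = df
        self._trees: dict[str, IntervalTree] = {}
        for chrom, grp in df.groupby("chrom"):
            self._trees[chrom] = IntervalTree.from_tuples(
                (s, e, k) for s, e, k in zip(grp["start"], grp["stop"], grp["key"]))
        self._by_key = {k: (c, s, e) for k, c, s, e in
                        zip(df["key"], df["chrom"], df["start"], df["stop"])}

    def __len__(self) -> int:
        return len(self.records)

    def __contains__(self, key: str) -> bool:
        return key in self._by_key

    def keys(self) -> list[str]:
        return list(self.records["key"])

    def interval(self, key: str) -> tuple[str, int, int]:
        """(chrom, start, stop) of a band key; KeyError if unknown."""
        return self._by_key[key]

    def overlapping(self, chrom: str, start: int, stop: int) -> list[str]:
        """Band keys with nonempty half-open intersection, in genomic order."""
        tree = self._trees.get(normalize_chrom(chrom))
        if tree is None:
            return []
        hits = tree.overlap(start, stop)
        return [iv.data for iv in sorted(hits)]

    def band_at(self, chrom: str, position: int) -> str | None:
        hits = self.overlapping(chrom, position, position + 1)
        return hits[0] if hits else None


def read_cytoband_map(path: str | Path) -> CytobandMap:
    """UCSC ``cytoBand.txt`` dialect: chrom, chromStart, chromEnd, name, gieStain."""
    try:
        df = pd.read_csv(path, sep="\t", header=None, comment="#",
                         names=["chrom", "start", "stop", "band", "stain"],
                         dtype={"chrom": str, "band": str, "stain": str})
    except pd.errors.EmptyDataError:
        df = pd.DataFrame(columns=["chrom", "start", "stop", "band", "stain"])
    return CytobandMap(df)


def write_cytoband_map(bands: CytobandMap, path: str | Path) -> None:
    out = bands.records[["chrom", "start", "stop", "band", "stain"]].copy()
    out["chrom"] = "chr" + out["chrom"]
    out.to_csv(path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# copy-number evidence
# ---------------------------------------------------------------------------

@dataclass
class ProbeRatioTrack:
    """Per-sample array-CGH probe log2(test/reference) ratios along the genome."""

    sample_id: str
    probes: pd.DataFrame  # columns chrom, position, log2_ratio

    def __post_init__(self) -> None:
        req = {"chrom", "position", "log2_ratio"}
        if not req.issubset(self.probes.columns):
            raise FormatError(f"probe track needs columns {sorted(req)}")
        df = self.probes
        if not np.isfinite(df["log2_ratio"]).all():
            raise ValidationError(
                f"track {self.sample_id}: non-finite log2 ratio")
        # each chromosome must form one contiguous block of sorted positions
        chroms = df["chrom"].to_numpy()
        blocks = [c for i, c in enumerate(chroms) if i == 0 or chroms[i - 1] != c]
        if len(blocks) != len(set(blocks)):
            raise ValidationError(
                f"track {self.sample_id}: probes not grouped by chromosome")
        for _, grp in df.groupby("chrom", sort=False):
            if (np.diff(grp["position"].to_numpy()) < 0).any():
                raise ValidationError(
                    f"track {self.sample_id}: probes not sorted by position")


GAIN = "gain"
LOSS = "loss"


@dataclass(frozen=True)
class SegmentCall:
    """One called copy-number aberration in one sample."""

    sample_id: str
    chrom: str
    start: int
    stop: int
    direction: str
    mean_log2_ratio: float
    n_probes: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "chrom", normalize_chrom(self.chrom))
        if self.start >= self.stop:
            raise ValidationError(
                f"segment {self.sample_id} {self.chrom}: empty interval")
        if self.direction not in (GAIN, LOSS):
            raise ValidationError(f"bad direction {self.direction!r}")
        if self.direction == GAIN and self.mean_log2_ratio <= 0:
            raise ValidationError("gain segment with non-positive mean log2 ratio")
        if self.direction == LOSS and self.mean_log2_ratio >= 0:
            raise ValidationError("loss segment with non-negative mean log2 ratio")
        if self.n_probes < MIN_PROBES:
            raise ValidationError(
                f"segment with {self.n_probes} probes; aberration filter "
                f"requires more than {MIN_PROBES - 1}")


SEG_COLUMNS = ["sample", "chrom", "start", "end", "num_probes", "mean_log2"]


def read_segments(path: str | Path,
                  gain_thr: float = GAIN_THRESHOLD,
                  loss_thr: float = LOSS_THRESHOLD,
                  min_probes: int = MIN_PROBES) -> list[SegmentCall]:
    """Read pre-called segments in SEG format, applying the aberration filter.

    Rows with |mean log2| at or inside the thresholds, or with fewer than
    ``min_probes`` probes, are dropped (counted in the module log) — the same
    filter the probe-level caller applies.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in SEG_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path.name}: missing SEG columns {missing}")
    calls: list[SegmentCall] = []
    n_dropped = 0
    for lineno, row in enumerate(df.itertuples(index=False), 2):
        try:
            mean = float(row.mean_log2)
            n_probes = int(row.num_probes)
            start, stop = int(row.start), int(row.end)
        except (TypeError, ValueError) as exc:
            raise FormatError(f"{path.name}: malformed row at line {lineno}") from exc
        if n_probes < min_probes or loss_thr <= mean <= gain_thr:
            n_dropped += 1
            continue
        calls.append(SegmentCall(
            sample_id=str(row.sample), chrom=str(row.chrom), start=start,
            stop=stop, direction=GAIN if mean > 0 else LOSS,
            mean_log2_ratio=mean, n_probes=n_probes))
    if n_dropped:
        logger.info("read_segments: dropped %d of %d rows failing the "
                    "aberration filter", n_dropped, len(df))
    return calls


def write_segments(calls: Iterable[SegmentCall], path: str | Path) -> None:
    rows = [(c.sample_id, c.chrom, c.start, c.stop, c.n_probes,
             c.mean_log2_ratio) for c in calls]
    pd.DataFrame(rows, columns=SEG_COLUMNS).to_csv(
        path, sep="\t", index=False, float_format="%.12g")


def read_probe_tracks(path: str | Path) -> list[ProbeRatioTrack]:
    """Combined probe table (sample, chrom, position, log2_ratio) -> one
    track per sample, probes sorted."""
    df = pd.read_csv(path, sep="\t")
    req = {"sample", "chrom", "position", "log2_ratio"}
    if not req.issubset(df.columns):
        raise FormatError(f"{Path(path).name}: needs columns {sorted(req)}")
    tracks = []
    for sample, grp in df.groupby("sample", sort=True):
        probes = (grp[["chrom", "position", "log2_ratio"]]
                  .astype({"chrom": str, "position": int, "log2_ratio": float})
                  .sort_values(["chrom", "position"], kind="stable")
                  .reset_index(drop=True))
        probes["chrom"] = probes["chrom"].map(normalize_chrom)
        tracks.append(ProbeRatioTrack(sample_id=str(sample), probes=probes))
    return tracks


def write_probe_tracks(tracks: Iterable[ProbeRatioTrack], path: str | Path) -> None:
    frames = []
    for t in tracks:
        df = t.probes.copy()
        df.insert(0, "sample", t.sample_id)
        frames.append(df)
    pd.concat(frames, ignore_index=True).to_csv(
        path, sep="\t", index=False, float_format="%.12g")


# ---------------------------------------------------------------------------
# target databases
# ---------------------------------------------------------------------------

@dataclass
class TargetDB:
    """One miRNA target-prediction database: a set of (mirna, gene) pairs."""

    db_name: str
    pairs: set[tuple[str, str]] = field(default_factory=set)

    def genes_of(self, mirna: str) -> set[str]:
        return {g for m, g in self.pairs if m == mirna}


def read_target_db(path: str | Path, db_name: str | None = None) -> TargetDB:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise FormatError(f"{path.name}: expected columns mirna, gene")
    pairs = list(zip(df.iloc[:, 0], df.iloc[:, 1]))
    seen = set()
    for p in pairs:
        if p in seen:
            raise FormatError(f"{path.name}: duplicate pair {p}")
        seen.add(p)
    return TargetDB(db_name=db_name or path.stem, pairs=seen)


def write_target_db(db: TargetDB, path: str | Path) -> None:
    pd.DataFrame(sorted(db.pairs), columns=["mirna", "gene"]).to_csv(
        path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# clinical covariates
# ---------------------------------------------------------------------------

CLINICAL_COLUMNS = ["age", "tumor_size", "stage", "grade", "ln_status",
                    "recurrence", "distant_met", "group"]


@dataclass
class ClinicalTable:
    """Per-sample clinical covariates; missing values are NaN/None and are
    removed listwise by consumers."""

    data: pd.DataFrame  # indexed by sample id

    def __post_init__(self) -> None:
        df = self.data
        missing = [c for c in CLINICAL_COLUMNS if c not in df.columns]
        if missing:
            raise FormatError(f"clinical table missing columns {missing}")
        if df.index.duplicated().any():
            raise FormatError("duplicate sample ids in clinical table")
        ages = df["age"].dropna()
        if (ages <= 0).any():
            bad = ages.index[ages <= 0][0]
            raise ValidationError(f"non-positive age for sample {bad!r}")
        for col, allowed in (("stage", STAGES), ("ln_status", BINARY),
                             ("recurrence", BINARY), ("distant_met", BINARY)):
            vals = set(df[col].dropna().unique()) - allowed
            if vals:
                raise ValidationError(f"{col}: unexpected values {sorted(vals)}")
        grades = set(df["grade"].dropna().unique()) - GRADES
        if grades:
            raise ValidationError(f"grade: unexpected values {sorted(grades)}")


def read_clinical_table(path: str | Path) -> ClinicalTable:
    df = pd.read_csv(path, index_col=0)
    df.index = df.index.astype(str)
    if "grade" in df.columns:
        df["grade"] = pd.to_numeric(df["grade"], errors="coerce").astype("Int64")
    return ClinicalTable(data=df)


def write_clinical_table(table: ClinicalTable, path: str | Path) -> None:
    out = table.data.copy()
    out.index.name = "sample"
    out.to_csv(path, float_format="%.12g")
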