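"""Copy-number aberration calling, cytoband penetrance and recurrent regions.

The caller is a deliberately simple run-based detector: a maximal run of
consecutive probes on one chromosome whose log2 ratios all lie strictly
beyond the gain (+0.25) or loss (-0.25) threshold, with more than 3 probes,
is emitted as one segment.  Penetrance is the cohort-level fraction of cases
carrying at least one aberration of a given direction overlapping a cytoband;
bands exceeding a recurrence threshold form the recurrent-region set used by
the expression/copy-number integration.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import (GAIN, GAIN_THRESHOLD, LOSS, LOSS_THRESHOLD, MIN_PROBES,
                 CytobandMap, Locus, ProbeRatioTrack, SegmentCall,
                 ValidationError, overlaps)

logger = logging.getLogger(__name__)

TIE = "tie"
NONE = "none"


def call_segments(track: ProbeRatioTrack,
                  gain_thr: float = GAIN_THRESHOLD,
                  loss_thr: float = LOSS_THRESHOLD,
                  min_probes: int = MIN_PROBES) -> list[SegmentCall]:
    """Call gain/loss segments from a sorted probe ratio track.

    Runs cannot cross chromosome boundaries and must be strictly beyond one
    threshold for every probe.  Segment extent is the half-open interval from
    the first probe position to one past the last probe position.
    """
    df = track.probes
    pos = df["position"].to_numpy()
    chroms = df["chrom"].to_numpy()
    for _, grp in df.groupby("chrom", sort=False):
        p = grp["position"].to_numpy()
        if (np.diff(p) < 0).any():
            raise ValidationError(
                f"track {track.sample_id}: probes not sorted within chromosome")
    ratio = df["log2_ratio"].to_numpy(dtype=float)
    state = np.zeros(len(ratio), dtype=int)
    state[ratio > gain_thr] = 1
    state[ratio < loss_thr] = -1

    calls: list[SegmentCall] = []
    i, n = 0, len(ratio)
    while i < n:
        if state[i] == 0:
            i += 1
            continue
        j = i
        while (j + 1 < n and state[j + 1] == state[i]
               and chroms[j + 1] == chroms[i]):
            j += 1
        run_len = j - i + 1
        if run_len >= min_probes:
            calls.append(SegmentCall(
                sample_id=track.sample_id, chrom=str(chroms[i]),
                start=int(pos[i]), stop=int(pos[j]) + 1,
                direction=GAIN if state[i] == 1 else LOSS,
                mean_log2_ratio=float(ratio[i:j + 1].mean()),
                n_probes=run_len))
        i = j + 1
    return calls


@dataclass
class CytobandPenetrance:
    """Per-band gain/loss penetrance across a cohort of cases."""

    table: pd.DataFrame  # index band key; gain_fraction, loss_fraction, dominant
    n_cases: int


def cytoband_penetrance(calls_per_case: dict[str, list[SegmentCall]],
                        bands: CytobandMap) -> CytobandPenetrance:
    """Fraction of cases with >= 1 overlapping call per (band, direction).

    A case contributes at most once per (band, direction) however many of its
    segments overlap the band.  Calls on chromosomes absent from the band map
    are excluded with a warning.
    """
    if not calls_per_case:
        raise ValidationError("penetrance requires at least one case")
    n_cases = len(calls_per_case)
    hits: dict[tuple[str, str], set[str]] = {}
    n_unmapped = 0
    for case, calls in calls_per_case.items():
        for call in calls:
            keys = bands.overlapping(call.chrom, call.start, call.stop)
            if not keys and call.chrom not in set(bands.records["chrom"]):
                n_unmapped += 1
                continue
            for key in keys:
                hits.setdefault((key, call.direction), set()).add(case)
    if n_unmapped:
        logger.warning("cytoband_penetrance: excluded %d calls on chromosomes "
                       "absent from the band map", n_unmapped)
    rows = []
    for key in bands.keys():
        g = len(hits.get((key, GAIN), ())) / n_cases
        l = len(hits.get((key, LOSS), ())) / n_cases
        if g == l == 0:
            dom = NONE
        elif g == l:
            dom = TIE
        else:
            dom = GAIN if g > l else LOSS
        rows.append((key, g, l, dom))
    table = pd.DataFrame(rows, columns=["band", "gain_fraction",
                                        "loss_fraction", "dominant"])
    table = table.set_index("band")
    return CytobandPenetrance(table=table, n_cases=n_cases)


@dataclass
class RecurrentRegionSet:
    """Cytobands whose gain or loss penetrance reaches a frequency threshold."""

    frequency_threshold: float
    members: set[tuple[str, str, float]] = field(default_factory=set)
    #: band -> set of qualifying directions (both present on a tie)
    directions: dict[str, set[str]] = field(default_factory=dict)

    @property
    def bands(self) -> set[str]:
        return set(self.directions)

    def tied(self, band: str) -> bool:
        return len(self.directions.get(band, ())) == 2


def recurrent_regions(pen: CytobandPenetrance,
                      threshold: float = 0.33) -> RecurrentRegionSet:
    """Bands with gain or loss penetrance >= threshold.

    Both directions qualify independently; a band recurrent in both is kept
    with both directions (the tie is visible via :meth:`RecurrentRegionSet.tied`).
    """
    if not 0 < threshold <= 1:
        raise ValidationError(f"threshold must be in (0, 1], got {threshold}")
    members: set[tuple[str, str, float]] = set()
    directions: dict[str, set[str]] = {}
    for band, row in pen.table.iterrows():
        for direction, frac in ((GAIN, row["gain_fraction"]),
                                (LOSS, row["loss_fraction"])):
            if frac >= threshold:
                members.add((band, direction, float(frac)))
                directions.setdefault(band, set()).add(direction)
    return RecurrentRegionSet(frequency_threshold=threshold, members=members,
                              directions=directions)


def genes_in_regions(genes: list[Locus], regions: RecurrentRegionSet,
                     bands: CytobandMap) -> set[str]:
    """Ids of genes overlapping any recurrent band (half-open intersection)."""
    out: set[str] = set()
    intervals = [(band, *bands.interval(band)) for band in regions.bands]
    for gene in genes:
        for _, chrom, start, stop in intervals:
            if gene.chrom == chrom and overlaps(gene.start, gene.stop, start, stop):
                out.add(gene.id)
                break
    return out


def penetrance_table(pen: CytobandPenetrance, bands: CytobandMap) -> pd.DataFrame:
    """Penetrance joined with band coordinates, for reporting/plot export."""
    coords = bands.records.set_index("key")[["chrom", "start", "stop"]]
    return coords.join(pen.table, how="left")
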