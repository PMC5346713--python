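"""Expression / copy-number integration: the concordance panel and target voting.

The core triage: take the significant differentially expressed miRNAs, keep
those whose genomic locus falls in a recurrently altered cytoband, and retain
the ones whose expression direction matches the band's copy-number direction
(up-regulated in a gained band, down-regulated in a lost band).  The
surviving panel's predicted target genes are then voted across prediction
databases (kept when at least two agree) and intersected with the genes
residing in the recurrent bands.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .cna import RecurrentRegionSet
from .de import DEResult
from .io import GAIN, LOSS, CytobandMap, Locus, TargetDB, ValidationError, overlaps

logger = logging.getLogger(__name__)


def expand_probe_id(probe_id: str) -> list[str]:
    """Expand a multi-miRNA probe label into member miRNA ids.

    Panel platforms collapse near-identical mature miRNAs onto one probe with
    a label like ``hsa-miR-520d-5p, 518a-5p, 527``; members after the first
    inherit the ``hsa-miR-`` prefix.
    """
    parts = [p.strip() for p in probe_id.split(",") if p.strip()]
    if len(parts) <= 1:
        return parts
    head = parts[0]
    prefix = head[:head.rindex("-") + 1] if "-" in head else ""
    expanded = [head]
    for part in parts[1:]:
        expanded.append(part if part.startswith(prefix.split("-")[0]) else
                        "-".join(head.split("-")[:2]) + "-" + part)
    return expanded


@dataclass(frozen=True)
class BandMapping:
    """One significant miRNA (probe) located in one recurrent cytoband."""

    mirna_id: str        # probe label as it appears in the expression matrix
    member_id: str       # expanded member miRNA whose locus matched
    band: str
    directions: frozenset[str]  # qualifying CNA direction(s) of the band


def map_de_mirnas_to_bands(de: list[DEResult], loci: list[Locus],
                           bands: CytobandMap,
                           regions: RecurrentRegionSet) -> list[BandMapping]:
    """Locate significant miRNAs inside recurrent cytobands.

    A probe is expanded to all member miRNAs and all their loci; each
    (probe, band) pair appears once per overlapping recurrent band.  MiRNAs
    without loci are logged and skipped; miRNAs outside every recurrent band
    are excluded.
    """
    by_id: dict[str, list[Locus]] = {}
    for locus in loci:
        by_id.setdefault(locus.id, []).append(locus)
    region_intervals = {band: bands.interval(band) for band in regions.bands}

    mappings: list[BandMapping] = []
    seen: set[tuple[str, str]] = set()
    n_missing = 0
    for rec in de:
        if not rec.significant:
            continue
        members = expand_probe_id(rec.mirna_id)
        any_locus = False
        for member in members:
            for locus in by_id.get(member, ()):
                any_locus = True
                for band, (chrom, start, stop) in region_intervals.items():
                    if locus.chrom == chrom and overlaps(
                            locus.start, locus.stop, start, stop):
                        if (rec.mirna_id, band) in seen:
                            continue
                        seen.add((rec.mirna_id, band))
                        mappings.append(BandMapping(
                            mirna_id=rec.mirna_id, member_id=member, band=band,
                            directions=frozenset(regions.directions[band])))
        if not any_locus:
            n_missing += 1
    if n_missing:
        logger.info("map_de_mirnas_to_bands: %d significant miRNAs had no "
                    "genomic locus", n_missing)
    return mappings


@dataclass(frozen=True)
class ConcordanceRecord:
    """Verdict for one (miRNA, band) pair: does the expression direction
    match the band's copy-number direction?"""

    mirna_id: str
    band: str
    cna_direction: str          # direction used for the verdict
    expression_direction: str   # up | down
    log2fc: float
    p_value: float
    concordant: bool
    ambiguous_direction: bool = False  # band recurrent in both directions


def concordant(cna_direction: str, log2fc: float) -> bool:
    """The concordance rule: gain with up-regulation or loss with
    down-regulation."""
    if cna_direction not in (GAIN, LOSS):
        raise ValidationError(f"bad CNA direction {cna_direction!r}")
    return (cna_direction == GAIN and log2fc > 0) or \
           (cna_direction == LOSS and log2fc < 0)


def concordance_filter(mappings: list[BandMapping],
                       de: list[DEResult]) -> list[ConcordanceRecord]:
    """Apply the concordance rule to each band mapping.

    For a band recurrent in both directions the verdict is positive if either
    direction matches, and the record is flagged ambiguous.  One record per
    (miRNA, band) pair; the concordant subset is the integration panel.
    """
    by_id = {r.mirna_id: r for r in de}
    records = []
    for m in mappings:
        rec = by_id.get(m.mirna_id)
        if rec is None:
            raise ValidationError(f"no DE record for mapped miRNA {m.mirna_id!r}")
        matching = sorted(d for d in m.directions if concordant(d, rec.log2fc))
        verdict = bool(matching)
        direction = matching[0] if matching else sorted(m.directions)[0]
        records.append(ConcordanceRecord(
            mirna_id=m.mirna_id, band=m.band, cna_direction=direction,
            expression_direction=rec.direction, log2fc=rec.log2fc,
            p_value=rec.p_value, concordant=verdict,
            ambiguous_direction=len(m.directions) > 1))
    return records


def concordant_panel(records: list[ConcordanceRecord]) -> list[ConcordanceRecord]:
    """The concordant subset, one record per miRNA (first band kept)."""
    seen: set[str] = set()
    panel = []
    for rec in records:
        if rec.concordant and rec.mirna_id not in seen:
            seen.add(rec.mirna_id)
            panel.append(rec)
    return panel


@dataclass
class VotedTargetSet:
    """Predicted target genes supported by at least ``min_support`` databases."""

    mirnas: set[str]
    genes: set[str]
    support: dict[str, set[str]] = field(default_factory=dict)  # gene -> dbs
    min_support: int = 2


def vote_targets(panel_mirnas: set[str] | list[str], dbs: list[TargetDB],
                 min_support: int = 2, pooled: bool = True) -> VotedTargetSet:
    """Vote predicted targets of the panel across prediction databases.

    In the default pooled mode, support for a gene is the set of databases
    predicting it for *any* panel miRNA; with ``pooled=False`` a gene is kept
    only if some single miRNA-gene pair reaches ``min_support`` databases.
    """
    if min_support > len(dbs):
        raise ValidationError(
            f"min_support={min_support} exceeds the {len(dbs)} databases supplied")
    panel = set(panel_mirnas)
    support: dict[str, set[str]] = {}
    pair_support: dict[tuple[str, str], set[str]] = {}
    for db in dbs:
        for mirna, gene in db.pairs:
            if mirna not in panel:
                continue
            support.setdefault(gene, set()).add(db.db_name)
            pair_support.setdefault((mirna, gene), set()).add(db.db_name)
    if pooled:
        genes = {g for g, s in support.items() if len(s) >= min_support}
    else:
        genes = {g for (m, g), s in pair_support.items() if len(s) >= min_support}
    return VotedTargetSet(mirnas=panel, genes=genes,
                          support={g: support[g] for g in genes},
                          min_support=min_support)


@dataclass
class TargetIntersection:
    """Overlap between voted targets and genes in the recurrent regions."""

    n_targets: int
    n_region_genes: int
    intersection: set[str]
    #: percent of voted targets eliminated by the region filter
    reduction_percent: float

    @property
    def n_common(self) -> int:
        return len(self.intersection)


def intersect_targets_with_region_genes(targets: VotedTargetSet,
                                        region_genes: set[str]) -> TargetIntersection:
    """Intersect voted target genes with genes located in recurrent bands.

    Run once per recurrence tier (e.g. bands altered in >= 33% and >= 40% of
    cases) to obtain the nested Venn counts.
    """
    common = targets.genes & region_genes
    n_targets = len(targets.genes)
    reduction = 100.0 * (1.0 - len(common) / n_targets) if n_targets else 0.0
    return TargetIntersection(n_targets=n_targets,
                              n_region_genes=len(region_genes),
                              intersection=common,
                              reduction_percent=reduction)
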