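"""Synthetic input bundles with planted ground truth.

The generator emulates the data shapes of a two-cohort miRNA panel study:
a panel of ~800 miRNA probes counted in two patient groups (24 vs 28
samples), array-CGH probe tracks for the case group, a cytoband map over a
small synthetic genome, three target-prediction databases, gene loci, and a
clinical covariate table.  Effects are planted with known truth at every
stage: differentially expressed miRNAs with log2 fold changes, recurrent
gain/loss regions carried by a fixed fraction of cases, a concordant subset
of DE miRNAs whose loci sit inside matching recurrent regions, and
miRNA-age associations.

Counts are negative-binomial (mean/dispersion parameterization) to emulate
the overdispersion of counting panels.  Copy-number regions are placed on
whole cytobands so that band-level frequency accounting is exact by
construction.  Each component draws from its own RNG sub-stream derived
from the bundle seed, so adding a component never perturbs earlier draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .io import (GAIN, LOSS, CLINICAL_COLUMNS, ClinicalTable, CytobandMap,
                 ExpressionMatrix, Locus, ProbeRatioTrack, SegmentCall,
                 TargetDB, write_clinical_table, write_cytoband_map,
                 write_expression_matrix, write_group_map, write_loci_bed,
                 write_probe_tracks, write_segments, write_target_db)


class ConfigurationError(ValueError):
    """Infeasible or inconsistent simulation configuration."""


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the generator; defaults emulate the study conditions
    (800 probes, 24 vs 28 samples, 256 DE miRNAs, 26 concordant)."""

    # expression
    n_mirnas: int = 800
    n_samples_a: int = 24
    n_samples_b: int = 28
    group_names: tuple[str, str] = ("AA", "NHW")
    n_de: int = 256
    de_log2fc_range: tuple[float, float] = (0.7, 3.1)
    nb_dispersion: float = 0.1
    baseline_mean_range: tuple[float, float] = (20.0, 2000.0)
    # genome layout
    n_chromosomes: int = 23
    chrom_length: int = 12_000_000
    bands_per_chrom: int = 8
    # copy number
    n_recurrent_regions: int = 8
    recurrent_frequency: float = 0.5
    n_cna_regions: int = 6            # background regions per case
    cna_gain_loss_ratio: float = 1.0
    cna_level: float = 0.3
    probe_spacing: int = 100_000
    probe_noise_sd: float = 0.01
    n_concordant: int = 26
    # targets
    target_db_count: int = 3
    n_genes: int = 2000
    target_rate: float = 0.02         # latent true-target rate per (miRNA, gene)
    db_sensitivity: float = 0.8       # chance a db reports a true target
    db_false_rate: float = 0.002      # chance a db reports a non-target
    # clinical
    age_mean: tuple[float, float] = (50.7, 53.7)
    age_sd: tuple[float, float] = (8.0, 11.4)
    n_age_associated: int = 3
    age_effect_log2_per_year: float = 0.03
    n_missing_clinical: int = 7
    seed: int = 0

    def validate(self) -> None:
        if not (0 <= self.n_concordant <= self.n_de <= self.n_mirnas):
            raise ConfigurationError(
                "need n_concordant <= n_de <= n_mirnas, got "
                f"{self.n_concordant}/{self.n_de}/{self.n_mirnas}")
        if self.n_age_associated > max(self.n_concordant, 0):
            raise ConfigurationError(
                "n_age_associated exceeds the planted concordant panel")
        for name in ("n_mirnas", "n_samples_a", "n_samples_b", "n_chromosomes",
                     "chrom_length", "bands_per_chrom", "probe_spacing",
                     "target_db_count", "n_genes"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        for name in ("recurrent_frequency", "target_rate", "db_sensitivity",
                     "db_false_rate"):
            if not 0 <= getattr(self, name) <= 1:
                raise ConfigurationError(f"{name} must lie in [0, 1]")
        n_bands = self.n_chromosomes * self.bands_per_chrom
        if self.n_recurrent_regions + self.n_cna_regions > n_bands:
            raise ConfigurationError(
                f"{self.n_recurrent_regions} recurrent + {self.n_cna_regions} "
                f"background regions do not fit {n_bands} cytobands")
        band_size = self.chrom_length // self.bands_per_chrom
        if band_size // self.probe_spacing < 10:
            raise ConfigurationError(
                "cytobands must span >= 10 probes so planted segments pass "
                "the caller's aberration filter")
        if self.cna_level <= 0.25:
            raise ConfigurationError(
                "planted |level| must exceed the 0.25 calling threshold")


@dataclass
class SimulationTruth:
    """Planted ground truth for scoring recovery at every stage."""

    de_log2fc: dict[str, float]                    # planted DE miRNAs
    concordant: dict[str, tuple[str, str, float]]  # mirna -> (band, dir, lfc)
    recurrent_regions: dict[str, tuple[str, float]]  # band -> (dir, frequency)
    segments: list[SegmentCall]                    # per-sample true segments
    age_effects: dict[str, float]                  # mirna -> log2 units / year
    mean_a: pd.Series                              # generating group means
    mean_b: pd.Series


@dataclass
class SyntheticBundle:
    """One complete, internally consistent input bundle."""

    config: SimulationConfig
    expression: ExpressionMatrix
    mirna_loci: list[Locus]
    cytobands: CytobandMap
    tracks: list[ProbeRatioTrack]
    target_dbs: list[TargetDB]
    genes: list[Locus]
    clinical: ClinicalTable
    truth: SimulationTruth


def _rng(config: SimulationConfig, component: int) -> np.random.Generator:
    # fixed per-component sub-streams: adding a component never shifts others
    return np.random.default_rng(np.random.SeedSequence((config.seed, component)))


_GENOME, _EXPRESSION, _CNA, _TARGETS, _CLINICAL = range(5)


def _chrom_names(config: SimulationConfig) -> list[str]:
    names = [str(i + 1) for i in range(min(config.n_chromosomes, 22))]
    if config.n_chromosomes >= 23:
        names.append("X")
    names += [f"C{i}" for i in range(24, config.n_chromosomes + 1)]
    return names[:config.n_chromosomes]


def _make_cytobands(config: SimulationConfig) -> CytobandMap:
    rows = []
    size = config.chrom_length // config.bands_per_chrom
    half = config.bands_per_chrom // 2
    for chrom in _chrom_names(config):
        for i in range(config.bands_per_chrom):
            label = f"p{half - i}" if i < half else f"q{i - half + 1}"
            rows.append((chrom, i * size, (i + 1) * size
                         if i < config.bands_per_chrom - 1 else config.chrom_length,
                         label, "gneg"))
    return CytobandMap(pd.DataFrame(rows, columns=["chrom", "start", "stop",
                                                   "band", "stain"]))


def _uniform_locus(rng: np.random.Generator, config: SimulationConfig,
                   chroms: list[str], length: int) -> tuple[str, int, int]:
    chrom = chroms[rng.integers(len(chroms))]
    start = int(rng.integers(0, config.chrom_length - length))
    return chrom, start, start + length


def generate_bundle(config: SimulationConfig | None = None,
                    **overrides) -> SyntheticBundle:
    """Generate a deterministic bundle with planted effects.

    Keyword overrides are applied on top of ``config`` (or the defaults), so
    ``generate_bundle(seed=7, n_de=0)`` gives a null bundle.
    """
    config = replace(config or SimulationConfig(), **overrides)
    config.validate()
    chroms = _chrom_names(config)
    bands = _make_cytobands(config)
    band_keys = bands.keys()

    # --- copy-number layout -------------------------------------------------
    rng_cna = _rng(config, _CNA)
    recurrent_keys = [band_keys[i] for i in sorted(
        rng_cna.choice(len(band_keys), size=config.n_recurrent_regions,
                       replace=False))]
    p_gain = config.cna_gain_loss_ratio / (1.0 + config.cna_gain_loss_ratio)
    recurrent_dir = {k: GAIN if rng_cna.random() < p_gain else LOSS
                     for k in recurrent_keys}
    group_a, group_b = config.group_names
    samples_a = [f"{group_a}_{i + 1:02d}" for i in range(config.n_samples_a)]
    samples_b = [f"{group_b}_{i + 1:02d}" for i in range(config.n_samples_b)]
    groups = {s: group_a for s in samples_a} | {s: group_b for s in samples_b}

    n_carriers = max(1, round(config.recurrent_frequency * config.n_samples_a))
    carriers = {k: sorted(rng_cna.choice(config.n_samples_a, size=n_carriers,
                                         replace=False))
                for k in recurrent_keys}
    recurrent_truth = {k: (recurrent_dir[k], n_carriers / config.n_samples_a)
                       for k in recurrent_keys}

    background_pool = [k for k in band_keys if k not in recurrent_dir]
    case_bands: dict[str, list[tuple[str, str]]] = {s: [] for s in samples_a}
    for k, cs in carriers.items():
        for ci in cs:
            case_bands[samples_a[ci]].append((k, recurrent_dir[k]))
    for s in samples_a:
        picks = rng_cna.choice(len(background_pool),
                               size=min(config.n_cna_regions,
                                        len(background_pool)), replace=False)
        for i in sorted(picks):
            direction = GAIN if rng_cna.random() < p_gain else LOSS
            case_bands[s].append((background_pool[i], direction))

    # --- miRNA loci and planted effects ------------------------------------
    rng_gen = _rng(config, _GENOME)
    mirna_ids = [f"syn-miR-{i + 1:04d}" for i in range(config.n_mirnas)]
    de_idx = sorted(rng_gen.choice(config.n_mirnas, size=config.n_de,
                                   replace=False))
    concordant_idx = de_idx[:config.n_concordant]
    lo, hi = config.de_log2fc_range
    magnitudes = rng_gen.uniform(lo, hi, size=config.n_de)

    de_log2fc: dict[str, float] = {}
    concordant_truth: dict[str, tuple[str, str, float]] = {}
    loci: list[Locus] = []
    recurrent_intervals = {k: bands.interval(k) for k in recurrent_keys}

    for rank, idx in enumerate(de_idx):
        mid = mirna_ids[idx]
        if rank < config.n_concordant:
            band = recurrent_keys[rank % len(recurrent_keys)]
            direction = recurrent_dir[band]
            lfc = magnitudes[rank] if direction == GAIN else -magnitudes[rank]
            chrom, bstart, bstop = recurrent_intervals[band]
            start = int(rng_gen.integers(bstart, bstop - 90))
            loci.append(Locus(id=mid, chrom=chrom, start=start, stop=start + 85))
            concordant_truth[mid] = (band, direction, float(lfc))
        else:
            # non-concordant DE miRNAs are kept out of recurrent bands so the
            # planted concordant set is the exact ground-truth panel
            lfc = float(magnitudes[rank] * rng_gen.choice([-1.0, 1.0]))
            chrom, start, stop = _uniform_locus(rng_gen, config, chroms, 85)
            while any(k in recurrent_dir
                      for k in bands.overlapping(chrom, start, stop)):
                chrom, start, stop = _uniform_locus(rng_gen, config, chroms, 85)
            loci.append(Locus(id=mid, chrom=chrom, start=start, stop=stop))
        de_log2fc[mid] = float(lfc)
    de_set = set(de_idx)
    for idx in range(config.n_mirnas):
        if idx in de_set:
            continue
        chrom, start, stop = _uniform_locus(rng_gen, config, chroms, 85)
        loci.append(Locus(id=mirna_ids[idx], chrom=chrom, start=start, stop=stop))
    loci.sort(key=lambda l: l.id)

    genes = []
    for i in range(config.n_genes):
        chrom, start, stop = _uniform_locus(rng_gen, config, chroms, 20_000)
        genes.append(Locus(id=f"GENE{i + 1:05d}", chrom=chrom, start=start,
                           stop=stop))

    # --- clinical covariates (needed before counts: age effects) ------------
    rng_cli = _rng(config, _CLINICAL)
    all_samples = samples_a + samples_b
    n_a, n_b = config.n_samples_a, config.n_samples_b
    ages = np.concatenate([
        np.clip(rng_cli.normal(config.age_mean[0], config.age_sd[0], n_a), 25, 90),
        np.clip(rng_cli.normal(config.age_mean[1], config.age_sd[1], n_b), 25, 90)])
    sizes = np.round(rng_cli.lognormal(np.log(2.5), 0.45, n_a + n_b), 1)
    stages = rng_cli.choice(["I", "II", "III"], size=n_a + n_b,
                            p=[0.0, 0.11, 0.89])
    grades = rng_cli.choice([1, 2, 3], size=n_a + n_b, p=[0.0, 0.12, 0.88])
    ln = np.where(rng_cli.random(n_a + n_b) <
                  np.r_[np.full(n_a, 0.50), np.full(n_b, 0.385)], "pos", "neg")
    rec = np.where(rng_cli.random(n_a + n_b) <
                   np.r_[np.full(n_a, 0.33), np.full(n_b, 0.10)], "pos", "neg")
    dm = np.where(rng_cli.random(n_a + n_b) <
                  np.r_[np.full(n_a, 0.26), np.full(n_b, 0.17)], "pos", "neg")
    clin = pd.DataFrame({
        "age": np.round(ages, 1), "tumor_size": sizes, "stage": stages,
        "grade": grades, "ln_status": ln, "recurrence": rec,
        "distant_met": dm,
        "group": [groups[s] for s in all_samples]}, index=all_samples)
    clin["grade"] = clin["grade"].astype("Int64")
    if config.n_missing_clinical:
        victims = rng_cli.choice(n_a + n_b,
                                 size=min(config.n_missing_clinical, n_a + n_b),
                                 replace=False)
        fields = rng_cli.choice(["tumor_size", "ln_status"], size=len(victims))
        for v, f in zip(victims, fields):
            clin.iloc[v, clin.columns.get_loc(f)] = np.nan
    clinical = ClinicalTable(data=clin[CLINICAL_COLUMNS])

    age_ids = [mirna_ids[i] for i in concordant_idx[:config.n_age_associated]]
    age_effects = {m: config.age_effect_log2_per_year for m in age_ids}

    # --- counts --------------------------------------------------------------
    rng_expr = _rng(config, _EXPRESSION)
    log_lo, log_hi = np.log(config.baseline_mean_range)
    base = np.exp(rng_expr.uniform(log_lo, log_hi, size=config.n_mirnas))
    lfc_vec = np.array([de_log2fc.get(m, 0.0) for m in mirna_ids])
    mean_a_vec = base * np.exp2(lfc_vec / 2.0)
    mean_b_vec = base * np.exp2(-lfc_vec / 2.0)
    means = np.empty((config.n_mirnas, n_a + n_b))
    means[:, :n_a] = mean_a_vec[:, None]
    means[:, n_a:] = mean_b_vec[:, None]
    centered_age = ages - ages.mean()
    for mid, beta in age_effects.items():
        i = mirna_ids.index(mid)
        means[i, :] = means[i, :] * np.exp2(beta * centered_age)
    if config.nb_dispersion > 0:
        size = 1.0 / config.nb_dispersion
        counts = rng_expr.negative_binomial(size, size / (size + means))
    else:
        counts = rng_expr.poisson(means)
    expression = ExpressionMatrix(
        values=pd.DataFrame(counts, index=mirna_ids, columns=all_samples),
        groups=pd.Series(groups), scale="raw_counts")

    # --- probe tracks --------------------------------------------------------
    positions = {c: np.arange(config.probe_spacing // 2, config.chrom_length,
                              config.probe_spacing) for c in chroms}
    n_per_chrom = len(positions[chroms[0]])
    tracks: list[ProbeRatioTrack] = []
    truth_segments: list[SegmentCall] = []
    for s in samples_a:
        level = {c: np.zeros(n_per_chrom) for c in chroms}
        for band, direction in case_bands[s]:
            chrom, bstart, bstop = bands.interval(band)
            mask = (positions[chrom] >= bstart) & (positions[chrom] < bstop)
            lvl = config.cna_level if direction == GAIN else -config.cna_level
            level[chrom][mask] += lvl
            truth_segments.append(SegmentCall(
                sample_id=s, chrom=chrom, start=bstart, stop=bstop,
                direction=direction, mean_log2_ratio=lvl,
                n_probes=int(mask.sum())))
        frames = []
        for c in chroms:
            noise = rng_cna.normal(0.0, config.probe_noise_sd, n_per_chrom)
            frames.append(pd.DataFrame({
                "chrom": c, "position": positions[c],
                "log2_ratio": level[c] + noise}))
        tracks.append(ProbeRatioTrack(
            sample_id=s, probes=pd.concat(frames, ignore_index=True)))

    # --- target databases ----------------------------------------------------
    rng_tgt = _rng(config, _TARGETS)
    gene_ids = [g.id for g in genes]
    true_targets: dict[str, np.ndarray] = {}
    for mid in mirna_ids:
        k = rng_tgt.binomial(config.n_genes, config.target_rate)
        true_targets[mid] = rng_tgt.choice(config.n_genes, size=k, replace=False)
    target_dbs = []
    for d in range(config.target_db_count):
        pairs: set[tuple[str, str]] = set()
        for mid in mirna_ids:
            tt = true_targets[mid]
            keep = tt[rng_tgt.random(len(tt)) < config.db_sensitivity]
            n_false = rng_tgt.binomial(config.n_genes, config.db_false_rate)
            false = rng_tgt.choice(config.n_genes, size=n_false, replace=False)
            for g in np.concatenate([keep, false]):
                pairs.add((mid, gene_ids[int(g)]))
        target_dbs.append(TargetDB(db_name=f"db{chr(ord('A') + d)}", pairs=pairs))

    truth = SimulationTruth(
        de_log2fc=de_log2fc, concordant=concordant_truth,
        recurrent_regions=recurrent_truth, segments=truth_segments,
        age_effects=age_effects,
        mean_a=pd.Series(mean_a_vec, index=mirna_ids),
        mean_b=pd.Series(mean_b_vec, index=mirna_ids))
    return SyntheticBundle(config=config, expression=expression,
                           mirna_loci=loci, cytobands=bands, tracks=tracks,
                           target_dbs=target_dbs, genes=genes,
                           clinical=clinical, truth=truth)


def truth_report(bundle: SyntheticBundle) -> dict[str, pd.DataFrame]:
    """Planted truth as tab-separable tables, for scoring recovery."""
    t = bundle.truth
    de = pd.DataFrame(sorted(t.de_log2fc.items()),
                      columns=["mirna", "log2fc"])
    panel = pd.DataFrame(
        [(m, b, d, l) for m, (b, d, l) in sorted(t.concordant.items())],
        columns=["mirna", "band", "direction", "log2fc"])
    segs = pd.DataFrame(
        [(s.sample_id, s.chrom, s.start, s.stop, s.direction,
          s.mean_log2_ratio, s.n_probes) for s in t.segments],
        columns=["sample", "chrom", "start", "stop", "direction",
                 "level", "n_probes"])
    regions = pd.DataFrame(
        [(b, d, f) for b, (d, f) in sorted(t.recurrent_regions.items())],
        columns=["band", "direction", "frequency"])
    age = pd.DataFrame(sorted(t.age_effects.items()),
                       columns=["mirna", "log2_per_year"])
    return {"truth_de": de, "truth_panel": panel, "truth_segments": segs,
            "truth_regions": regions, "truth_age_effects": age}


def write_bundle(bundle: SyntheticBundle, outdir: str | Path) -> dict[str, Path]:
    """Write the bundle in the pipeline's on-disk formats plus truth tables.

    Returns a manifest of the written paths; a ready-to-use ``config.yaml``
    pointing at them is included.
    """
    import yaml

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "expression": outdir / "expression.tsv",
        "groups": outdir / "groups.tsv",
        "mirna_loci": outdir / "mirna_loci.bed",
        "cytobands": outdir / "cytobands.txt",
        "probes": outdir / "probes.tsv",
        "genes": outdir / "genes.bed",
        "clinical": outdir / "clinical.csv",
    }
    write_expression_matrix(bundle.expression, paths["expression"])
    write_group_map(dict(bundle.expression.groups), paths["groups"])
    write_loci_bed(bundle.mirna_loci, paths["mirna_loci"])
    write_cytoband_map(bundle.cytobands, paths["cytobands"])
    write_probe_tracks(bundle.tracks, paths["probes"])
    write_loci_bed(bundle.genes, paths["genes"])
    write_clinical_table(bundle.clinical, paths["clinical"])
    target_paths = {}
    for db in bundle.target_dbs:
        p = outdir / f"targets_{db.db_name}.tsv"
        write_target_db(db, p)
        target_paths[db.db_name] = str(p)
    for name, table in truth_report(bundle).items():
        p = outdir / f"{name}.tsv"
        table.to_csv(p, sep="\t", index=False, float_format="%.12g")
        paths[name] = p
    write_segments(bundle.truth.segments, outdir / "truth_calls.seg")

    cfg = {
        "expression": str(paths["expression"]),
        "groups": str(paths["groups"]),
        "mirna_loci": str(paths["mirna_loci"]),
        "cytobands": str(paths["cytobands"]),
        "probes": str(paths["probes"]),
        "genes": str(paths["genes"]),
        "clinical": str(paths["clinical"]),
        "target_dbs": target_paths,
        "thresholds": {
            "alpha_p": 0.01, "alpha_q": 0.05,
            "gain_threshold": 0.25, "loss_threshold": -0.25, "min_probes": 4,
            "recurrence_threshold": 0.33, "min_support": 2,
        },
    }
    config_path = outdir / "config.yaml"
    with open(config_path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)
    paths["config"] = config_path
    return paths
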