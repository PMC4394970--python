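"""Seeded generators for every input the pipeline consumes, with ground truth.

The generators emulate the structure of the study's three data
sources so each stage is testable without external downloads:

* expression matrices (RPKM-like genes / RPM-like miRNA families)
  with log-normal noise around gene-specific baselines, planted
  log2-scale group shifts for differential features, and a monotone
  per-stage increment for designated stage-trend biomarker genes
  (default group layout mirrors a clear-cell kidney-carcinoma cohort:
  31 normal, 197 T1, 49 T2, 162 T3, 6 T4);
* random-background 3'UTRs with 8mer seed sites planted for chosen
  miRNA families at stated fractions of upregulated and background
  genes (accidental background matches are allowed and deliberately
  not recorded — detection must find them from sequence alone);
* two label-swapped 4-plex reporter-ion runs with per-channel
  efficiency factors and multiplicative log-normal noise;
* per-sample immunostain intensity (IOD) values drawn normally per
  group, with an exact mode that rescales draws to hit the requested
  (mean, SD) to machine precision so printed-table statistics can be
  reproduced from raw samples.

Every generator is deterministic for a fixed seed, and everything
planted is recorded in a TruthBundle exactly as injected.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dataio import ExpressionMatrix
from .itraq import ReporterRunTable
from .seed_targets import MirnaFamily, SeedSite, seed_match_patterns

__all__ = [
    "TruthBundle",
    "KIRC_STAGE_GROUPS",
    "gen_expression",
    "gen_utrs",
    "gen_itraq",
    "gen_iod",
    "write_study_inputs",
]

#: stage-group sample counts of the emulated kidney-carcinoma cohort
KIRC_STAGE_GROUPS = {"normal": 31, "T1": 197, "T2": 49, "T3": 162, "T4": 6}

_STAGE_RANKS = {"normal": 0, "T1": 1, "T2": 2, "T3": 3, "T4": 4,
                "G1": 1, "G2": 2, "G3": 3, "G4": 4}


@dataclass
class TruthBundle:
    """Ground truth for everything a generator planted."""

    de_genes_up: dict = field(default_factory=dict)      # gene -> log2 effect
    de_mirnas_down: dict = field(default_factory=dict)   # family -> log2 effect
    planted_sites: list = field(default_factory=list)    # SeedSite records
    itraq_true_ratios: dict = field(default_factory=dict)  # protein -> (RH, RC, RM)
    iod_group_params: dict = field(default_factory=dict)   # group -> (n, mean, sd)
    stage_trend_genes: list = field(default_factory=list)

    def merge(self, other: "TruthBundle") -> "TruthBundle":
        return TruthBundle(
            de_genes_up={**self.de_genes_up, **other.de_genes_up},
            de_mirnas_down={**self.de_mirnas_down, **other.de_mirnas_down},
            planted_sites=self.planted_sites + other.planted_sites,
            itraq_true_ratios={**self.itraq_true_ratios, **other.itraq_true_ratios},
            iod_group_params={**self.iod_group_params, **other.iod_group_params},
            stage_trend_genes=self.stage_trend_genes + other.stage_trend_genes,
        )


def gen_expression(
    n_genes: int,
    group_sizes: dict | None = None,
    n_de: int = 0,
    effect_log2: float = 2.0,
    stage_trend_genes: list | None = None,
    trend_step_log2: float = 0.5,
    noise_sd: float = 1.0,
    seed: int = 0,
    feature_prefix: str = "G",
    control_group: str = "normal",
    unit: str = "RPKM",
) -> tuple[ExpressionMatrix, TruthBundle]:
    """Log-normal expression matrix with planted differential features.

    Each feature gets a log2 baseline ~ Uniform(2, 7); a sample's
    log2 value adds the planted effect (differential features, in
    every non-control group), a per-stage trend increment
    (rank * trend_step_log2, for designated stage-trend genes) and
    Normal(0, noise_sd) noise. noise_sd is in log2 units (default 1,
    a realistic dispersion for RPKM-scale data). With noise_sd = 0
    and effect_log2 = e the tumor/control mean ratio of every
    differential feature is exactly 2**e.

    A positive effect plants upregulated features (recorded in
    de_genes_up); a negative effect plants downregulated ones
    (recorded in de_mirnas_down). effect_log2 = 0 with n_de > 0 is an
    error — the truth could never be recovered.
    """
    if group_sizes is None:
        group_sizes = dict(KIRC_STAGE_GROUPS)
    if control_group not in group_sizes:
        raise ValueError(f"group_sizes must include the control group {control_group!r}")
    if n_de > n_genes:
        raise ValueError(f"n_de={n_de} exceeds n_genes={n_genes}")
    if n_de > 0 and effect_log2 == 0:
        raise ValueError("effect_log2 = 0 with n_de > 0: planted truth would be unrecoverable")

    rng = np.random.default_rng(seed)
    width = len(str(max(n_genes, 1)))
    genes = [f"{feature_prefix}{i:0{width}d}" for i in range(n_genes)]
    de_idx = rng.choice(n_genes, size=n_de, replace=False) if n_de else np.array([], dtype=int)
    de_set = set(de_idx.tolist())
    trend_set = set(stage_trend_genes or [])
    unknown_trend = trend_set - set(genes)
    if unknown_trend:
        raise ValueError(f"stage_trend_genes not in generated gene set: {sorted(unknown_trend)}")

    baselines = rng.uniform(2.0, 7.0, size=n_genes)
    sample_ids, sample_groups = [], []
    for g, size in group_sizes.items():
        for j in range(size):
            sample_ids.append(f"{g}_s{j:03d}")
            sample_groups.append(g)
    n_samples = len(sample_ids)
    ranks = {g: _STAGE_RANKS.get(g, i) for i, g in enumerate(group_sizes)}

    log2vals = np.tile(baselines[:, None], (1, n_samples))
    group_arr = np.array(sample_groups)
    tumor_cols = np.where(group_arr != control_group)[0]
    if len(de_set) and tumor_cols.size:
        log2vals[np.ix_(sorted(de_set), tumor_cols)] += effect_log2
    if trend_set:
        trend_idx = [i for i, gene in enumerate(genes) if gene in trend_set]
        for g in group_sizes:
            if g == control_group:
                continue
            cols = np.where(group_arr == g)[0]
            log2vals[np.ix_(trend_idx, cols)] += trend_step_log2 * ranks[g]
    if noise_sd > 0:
        log2vals = log2vals + rng.normal(0.0, noise_sd, size=log2vals.shape)

    values = pd.DataFrame(np.exp2(log2vals), index=genes, columns=sample_ids)
    groups = pd.Series(sample_groups, index=sample_ids, name="group")
    matrix = ExpressionMatrix(values=values, groups=groups, unit=unit, ordinal_rank=ranks)

    truth = TruthBundle(stage_trend_genes=sorted(trend_set))
    planted = {genes[i]: effect_log2 for i in sorted(de_set)}
    if effect_log2 > 0:
        truth.de_genes_up = planted
    else:
        truth.de_mirnas_down = planted
    return matrix, truth


def gen_utrs(
    genes: list[str],
    families: list[MirnaFamily],
    target_fraction_in_up: float = 0.3,
    target_fraction_background: float = 0.05,
    utr_length: int = 500,
    seed: int = 0,
    up_genes: list[str] | None = None,
) -> tuple[list[tuple[str, str]], TruthBundle]:
    """Random-background UTRs with planted 8mer sites per family.

    For each family, an 8mer site is written into a round(fraction *
    count) subset of the upregulated genes and of the remaining
    background genes, at a position chosen uniformly among slots that
    do not overlap a previously planted site in that gene. Planted
    positions are recorded; accidental matches arising in the random
    background are allowed and not recorded.
    """
    if not (0 <= target_fraction_in_up <= 1 and 0 <= target_fraction_background <= 1):
        raise ValueError("target fractions must lie in [0, 1]")
    if utr_length < 8:
        raise ValueError(f"utr_length={utr_length} is shorter than an 8mer site")
    up = [g for g in (up_genes or []) if g in set(genes)]
    up_set = set(up)
    background = [g for g in genes if g not in up_set]

    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    char_matrix = bases[rng.integers(0, 4, size=(len(genes), utr_length))]
    row_of = {g: i for i, g in enumerate(genes)}
    seqs = {g: char_matrix[row_of[g]] for g in genes}
    occupied: dict[str, list[tuple[int, int]]] = {g: [] for g in genes}
    truth = TruthBundle()

    def plant(gene: str, fam: MirnaFamily) -> None:
        pattern = seed_match_patterns(fam)["8mer"]
        slots = [
            s for s in range(utr_length - len(pattern) + 1)
            if all(e <= s or s + len(pattern) <= b for b, e in occupied[gene])
        ]
        if not slots:
            return  # gene saturated with planted sites; leave unrecorded
        start = int(rng.choice(slots))
        seqs[gene][start:start + len(pattern)] = np.array(list(pattern))
        occupied[gene].append((start, start + len(pattern)))
        truth.planted_sites.append(
            SeedSite(gene=gene, family=fam.name, site_type="8mer",
                     start=start, end=start + len(pattern))
        )

    for fam in families:
        for pool, frac in ((up, target_fraction_in_up), (background, target_fraction_background)):
            n_pick = int(round(frac * len(pool)))
            if n_pick == 0:
                continue
            picked = rng.choice(len(pool), size=n_pick, replace=False)
            for idx in sorted(picked.tolist()):
                plant(pool[idx], fam)

    records = [(g, "".join(seqs[g])) for g in genes]
    return records, truth


def gen_itraq(
    n_proteins: int,
    true_ratios: dict | None = None,
    channel_efficiency_cv: float = 0.0,
    noise_cv: float = 0.0,
    seed: int = 0,
) -> tuple[ReporterRunTable, ReporterRunTable, TruthBundle]:
    """Two label-swapped 4-plex reporter runs with known protein ratios.

    true_ratios maps protein ids to (R:H, R:C, R:M); proteins not
    named get (1, 1, 1), so the bulk of the proteome is unchanged and
    median-ratio normalization to the reference channel is well
    posed. Intensity = per-run base abundance x group level x
    per-channel efficiency x multiplicative log-normal noise, with
    the efficiency factors and noise drawn at the stated coefficients
    of variation. Run 1 labels (114:H, 115:R, 116:C, 117:M); run 2
    swaps to (114:R, 115:H, 116:M, 117:C).
    """
    true_ratios = dict(true_ratios or {})
    for prot, r in true_ratios.items():
        if any(x <= 0 for x in r):
            raise ValueError(f"protein {prot!r}: ratios must be positive, got {r}")
    width = len(str(max(n_proteins, 1)))
    named = list(true_ratios)
    if len(named) > n_proteins:
        raise ValueError("more named proteins than n_proteins")
    filler = [f"P{i:0{width}d}" for i in range(n_proteins - len(named))]
    proteins = named + filler
    ratios = {p: tuple(map(float, true_ratios.get(p, (1.0, 1.0, 1.0)))) for p in proteins}

    rng = np.random.default_rng(seed)
    maps = [
        {"114": "H", "115": "R", "116": "C", "117": "M"},
        {"114": "R", "115": "H", "116": "M", "117": "C"},
    ]
    sigma_eff = float(np.sqrt(np.log1p(channel_efficiency_cv**2)))
    sigma_noise = float(np.sqrt(np.log1p(noise_cv**2)))
    runs = []
    for run_idx, cmap in enumerate(maps):
        base = np.exp(rng.normal(np.log(1e5), 1.0, size=n_proteins))
        eff = {ch: float(np.exp(rng.normal(0.0, sigma_eff))) if sigma_eff else 1.0
               for ch in cmap}
        data = {}
        for ch, grp in cmap.items():
            level = np.array([
                {"H": 1.0, "R": ratios[p][0],
                 "C": ratios[p][0] / ratios[p][1],
                 "M": ratios[p][0] / ratios[p][2]}[grp]
                for p in proteins
            ])
            col = base * level * eff[ch]
            if sigma_noise:
                col = col * np.exp(rng.normal(0.0, sigma_noise, size=n_proteins))
            data[ch] = col
        runs.append(
            ReporterRunTable(
                run_id=f"run{run_idx + 1}",
                intensities=pd.DataFrame(data, index=proteins),
                channel_to_group=cmap,
                gene_symbols={p: p for p in proteins},
            )
        )
    truth = TruthBundle(itraq_true_ratios=ratios)
    return runs[0], runs[1], truth


def gen_iod(
    group_params: dict,
    seed: int = 0,
    exact: bool = False,
) -> tuple[pd.DataFrame, TruthBundle]:
    """Per-sample immunostain IOD values drawn normally per group.

    group_params maps group -> (n, mean, sd). In exact mode each
    group's draws are affinely rescaled so the sample mean and n-1 SD
    match the request to machine precision — printed-table F values
    then reproduce from the raw samples. SD = 0 yields constant
    samples equal to the mean.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for group, (n, mean, sd) in group_params.items():
        n = int(n)
        if n < 2:
            raise ValueError(f"group {group!r}: n must be >= 2, got {n}")
        if sd < 0:
            raise ValueError(f"group {group!r}: SD must be non-negative")
        if sd == 0:
            vals = np.full(n, float(mean))
        else:
            vals = rng.normal(float(mean), float(sd), size=n)
            if exact:
                s = vals.std(ddof=1)
                if s == 0:
                    raise ValueError(f"group {group!r}: degenerate draw cannot be rescaled")
                vals = float(mean) + (vals - vals.mean()) * (float(sd) / s)
        for j, v in enumerate(vals):
            rows.append({"sample": f"{group}_s{j:03d}", "group": group, "value": float(v)})
    table = pd.DataFrame(rows)
    truth = TruthBundle(iod_group_params={g: tuple(p) for g, p in group_params.items()})
    return table, truth


def write_study_inputs(
    outdir,
    seed: int = 0,
    n_genes: int = 2000,
    n_de_genes: int = 100,
    n_mirnas: int = 60,
    n_de_mirnas: int = 4,
    n_normal: int = 30,
    n_tumor: int = 30,
    n_proteins: int = 100,
    n_biomarkers: int = 2,
    utr_length: int = 300,
    effect_log2: float = 3.0,
) -> tuple[dict, TruthBundle]:
    """Generate and write a complete, mutually consistent input bundle.

    Produces everything a full pipeline run consumes — gene and miRNA
    matrices with annotations, 3'UTR FASTA with sites planted for the
    downregulated families among the upregulated genes, two
    label-swapped reporter runs whose differential proteins are the
    first planted biomarker genes, and an immunostain IOD table —
    plus a merged TruthBundle. Returns (input manifest, truth); the
    manifest plugs straight into run_full.
    """
    from pathlib import Path

    from .dataio import write_fasta_utrs, write_matrix
    from .seed_targets import write_families

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)

    gene_matrix, gene_truth = gen_expression(
        n_genes, {"normal": n_normal, "T1": n_tumor}, n_de=n_de_genes,
        effect_log2=effect_log2, seed=int(rng.integers(2**31)),
    )
    write_matrix(gene_matrix, outdir / "genes.tsv", outdir / "genes_annotation.tsv")

    mirna_matrix, mirna_truth = gen_expression(
        n_mirnas, {"normal": n_normal, "T1": n_tumor}, n_de=n_de_mirnas,
        effect_log2=-effect_log2, seed=int(rng.integers(2**31)),
        feature_prefix="mir", unit="RPM",
    )
    write_matrix(mirna_matrix, outdir / "mirnas.tsv", outdir / "mirnas_annotation.tsv")

    fam_rng = np.random.default_rng(int(rng.integers(2**31)))
    families = [
        MirnaFamily(name=f, mature="".join(fam_rng.choice(list("ACGU"), size=22)))
        for f in mirna_matrix.features
    ]
    write_families(families, outdir / "families.tsv")

    up_genes = sorted(gene_truth.de_genes_up)
    down_families = [f for f in families if f.name in mirna_truth.de_mirnas_down]
    utrs, utr_truth = gen_utrs(
        gene_matrix.features, down_families, 0.6, 0.05, utr_length,
        seed=int(rng.integers(2**31)), up_genes=up_genes,
    )
    write_fasta_utrs(utrs, outdir / "utrs.fasta")

    biomarkers = up_genes[:n_biomarkers]
    true_ratios = {g: (4.0, 3.5, 2.2) for g in biomarkers}
    run1, run2, itraq_truth = gen_itraq(
        n_proteins, true_ratios, channel_efficiency_cv=0.2, noise_cv=0.05,
        seed=int(rng.integers(2**31)),
    )
    for i, run in enumerate((run1, run2), start=1):
        table = pd.DataFrame({"protein": run.proteins,
                              "gene": [run.gene_symbols[p] for p in run.proteins]})
        for ch in run.intensities.columns:
            table[ch] = run.intensities[ch].to_numpy()
        table.to_csv(outdir / f"itraq_run{i}.tsv", sep="\t", index=False)
        pd.DataFrame({"channel": list(run.channel_to_group),
                      "group": list(run.channel_to_group.values())}).to_csv(
            outdir / f"itraq_map{i}.tsv", sep="\t", index=False)

    iod_params = {
        "renal cyst": (9, 698.31, 298.01),
        "renal hamartoma": (9, 745.14, 229.71),
        "normal kidney": (15, 314.67, 148.06),
        "RCC": (16, 697.06, 445.88),
    }
    iod, iod_truth = gen_iod(iod_params, seed=int(rng.integers(2**31)), exact=True)
    iod.to_csv(outdir / "iod.tsv", sep="\t", index=False)

    truth = (gene_truth.merge(mirna_truth).merge(utr_truth)
             .merge(itraq_truth).merge(iod_truth))
    inputs = {
        "gene_matrix": str(outdir / "genes.tsv"),
        "gene_annotation": str(outdir / "genes_annotation.tsv"),
        "mirna_matrix": str(outdir / "mirnas.tsv"),
        "mirna_annotation": str(outdir / "mirnas_annotation.tsv"),
        "case_group": "T1",
        "control_group": "normal",
        "utr_fasta": str(outdir / "utrs.fasta"),
        "families": str(outdir / "families.tsv"),
        "itraq_run1": str(outdir / "itraq_run1.tsv"),
        "itraq_map1": str(outdir / "itraq_map1.tsv"),
        "itraq_run2": str(outdir / "itraq_run2.tsv"),
        "itraq_map2": str(outdir / "itraq_map2.tsv"),
        "iod_table": str(outdir / "iod.tsv"),
    }
    return inputs, truth
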