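"""Synthetic inputs for every pipeline stage, with planted ground truth.

The generator emulates the statistical structure the pipeline assumes:

* several case/control expression studies on different "platforms"
  (disjoint probeset namespaces, shared gene symbols) with a common set of
  genes shifted down in disease across brain compartments, ~1% array control
  probesets, and detection calls derived from intensity;
* a healthy-brain compendium in which one gene is expressed higher in a
  subset of one gender, so the per-sample scan flags mostly that gender;
* three case/control genotype cohorts with Hardy-Weinberg SNPs on one
  chromosome, where a single common SNP inside a designated gene carries
  disease risk only in one gender x APOE4 subset;
* compound-treatment profiles in which a few compounds elevate a target
  gene's probesets.

All randomness flows from ``SimulationConfig.seed`` through per-stream
``numpy`` generators, so identical configs give byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from admeta.expression import ExpressionStudy
from admeta.genetics import GeneRegion, GenerationError, GenotypeStudy, STRICT_WINDOW
from admeta.scan import CompendiumDataset, SampleCompendium
from admeta.compounds import ProfileSet


class ConfigurationError(ValueError):
    pass


#: Default planted disease signature: 24 genes consistently down in disease.
DEFAULT_PLANTED_GENES: tuple[str, ...] = (
    "AP3B2", "ATP1A3", "ATP5B", "ATP6V1E1", "ATP6V1G2", "BNIP3",
    "C14orf132", "C14orf2", "CACNG3", "GNG3", "GOT2", "MAGED1",
    "MRPS11", "NEUROD6", "PPP1R11", "PTPRN2", "RGS7", "SLC17A7",
    "SLC25A11", "SNAP25", "SYP", "TPI1", "UQCRC1", "YWHAB",
)

DEFAULT_COMPOUND_NAMES: tuple[str, ...] = ("valproic acid", "sodium phenylbutyrate")


@dataclass
class SimulationConfig:
    """All knobs of the synthetic cohort collection.

    Expression-study defaults mirror a small multi-study design (5 studies,
    10 + 10 samples per group per compartment, disease shift of 2 log2 units
    against residual noise of 0.5 log2 units).  Genotype defaults mirror a
    trio of cohorts of ~300 cases / ~300 controls each, APOE4-carrier
    fraction 0.45, a planted common risk variant (MAF 0.3, allelic odds
    ratio 3) effective only in APOE4+ females.  The compendium defaults
    mirror a 173-sample brain collection with 91 males.
    """

    seed: int = 0

    # --- expression studies ---
    n_studies: int = 5
    probesets_per_study: int = 2000
    samples_per_group: int = 10  # per compartment
    planted_down_genes: tuple[str, ...] = DEFAULT_PLANTED_GENES
    effect_size: float = 2.0  # log2 shift, disease below control
    noise_sd: float = 0.5  # log2 residual sd
    compartments: tuple[str, ...] = ("cortex", "hippocampus")
    control_probe_fraction: float = 0.01
    probesets_per_gene: int = 2

    # --- sample compendium ---
    gender_biased_gene: str = "NEUROD6"
    gender_bias_shift: float = 3.0  # in noise-sd units of the compendium
    biased_gender: str = "M"
    gender_bias_penetrance: float = 0.42
    compendium_size: int = 173
    compendium_male_fraction: float = 91 / 173
    compendium_probesets: int = 1000

    # --- genotype studies ---
    n_snp_studies: int = 3
    snps_per_study: int = 120
    cases_per_study: int = 300
    controls_per_study: int = 300
    disease_prevalence: float = 0.1
    target_gene: str = "NEUROD6"
    target_subset: str = "F+"  # gender (M/F) x APOE4 (+/-)
    risk_or: float = 3.0
    target_maf: float = 0.3
    maf_range: tuple[float, float] = (0.05, 0.5)
    apoe4_frequency: float = 0.45
    chrom: str = "chr1"
    chrom_length: int = 50_000_000
    gene_spacing: int = 2_000_000
    gene_length: int = 10_000

    # --- compound profiles ---
    n_profiles: int = 60
    planted_compounds: tuple[str, ...] = DEFAULT_COMPOUND_NAMES
    compound_target_gene: str = "NEUROD6"
    compound_shift: float = 4.0
    profile_probesets: int = 1000
    cell_lines: tuple[str, ...] = ("MCF7", "PC3")

    def __post_init__(self) -> None:
        problems = []
        if self.effect_size < 0:
            problems.append("effect_size must be >= 0")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            problems.append("maf_range must lie within (0, 0.5]")
        if not 0 < self.target_maf <= 0.5:
            problems.append("target_maf must lie within (0, 0.5]")
        if self.risk_or <= 0:
            problems.append("risk_or must be positive")
        if self.target_subset not in ("F+", "F-", "M+", "M-"):
            problems.append("target_subset must be one of F+, F-, M+, M-")
        if not 0 < self.disease_prevalence < 1:
            problems.append("disease_prevalence must be in (0, 1)")
        if min(self.cases_per_study, self.controls_per_study) < 1:
            problems.append("need >= 1 case and control per study")
        if self.samples_per_group < 2:
            problems.append("samples_per_group must be >= 2")
        if len(self.compartments) < 2:
            problems.append("need >= 2 compartments")
        if problems:
            raise ConfigurationError("; ".join(problems))

    def rng(self, stream: int) -> np.random.Generator:
        """Independent generator for one simulation stream."""
        return np.random.default_rng([self.seed, stream])


# stream ids, one per independent source of randomness
_EXPR, _COMPENDIUM, _GENO, _PROFILES, _TISSUE = 11, 22, 33, 44, 55


# ---------------------------------------------------------------- expression

def _probe_universe(cfg: SimulationConfig, study_idx: int) -> tuple[pd.Index, pd.Series]:
    """Per-study probeset ids and probeset -> gene map.

    Planted genes come first (``probesets_per_gene`` probesets each), then a
    shared background gene universe, then AFFX- control probesets mapped to
    no gene.
    """
    n_control = max(1, int(round(cfg.probesets_per_study * cfg.control_probe_fraction)))
    n_biological = cfg.probesets_per_study - n_control
    genes: list[str] = []
    for g in cfg.planted_down_genes:
        genes.extend([g] * cfg.probesets_per_gene)
    n_bg = n_biological - len(genes)
    if n_bg < 0:
        raise ConfigurationError("probesets_per_study too small for planted genes")
    for i in range(n_bg):
        genes.append(f"GENE{i // cfg.probesets_per_gene:05d}")
    probes = [f"s{study_idx}_ps{i:05d}" for i in range(n_biological)]
    probes += [f"AFFX-ctrl-s{study_idx}-{i:03d}" for i in range(n_control)]
    probe_map = pd.Series(genes, index=pd.Index(probes[:n_biological], name="probeset"))
    return pd.Index(probes, name="probeset"), probe_map


def _pa_from_intensity(values: pd.DataFrame, absent_below: float = 5.0,
                       present_above: float = 6.5) -> pd.DataFrame:
    """Detection calls from two intensity thresholds: A below the lower,
    M between, P above — the filter's semantics without probe-level data."""
    codes = np.full(values.shape, "M", dtype=object)
    arr = values.to_numpy()
    codes[arr < absent_below] = "A"
    codes[arr >= present_above] = "P"
    return pd.DataFrame(codes, index=values.index, columns=values.columns)


def simulate_expression_studies(cfg: SimulationConfig) -> list[ExpressionStudy]:
    """Case/control expression studies with a shared planted down-signature.

    Each study has all configured compartments with ``samples_per_group``
    cases and controls per compartment, Gaussian log2 expression around a
    per-probeset baseline, the planted genes shifted down by ``effect_size``
    in cases in *every* compartment, and P/A calls thresholded from
    intensity.  A disease-severity score (NFT-like, higher in cases) is
    attached to every sample.
    """
    rng = cfg.rng(_EXPR)
    planted = set(cfg.planted_down_genes)
    studies = []
    for si in range(cfg.n_studies):
        probes, probe_map = _probe_universe(cfg, si)
        # planted probesets stay well expressed so detection calls pass QC
        baseline = rng.uniform(4.0, 12.0, size=len(probes))
        planted_mask = np.array([probe_map.get(p, "") in planted for p in probes])
        baseline[planted_mask] = rng.uniform(8.0, 12.0, size=int(planted_mask.sum()))

        sample_ids, groups, comps, genders, scores = [], [], [], [], []
        for comp in cfg.compartments:
            for grp, n in (("case", cfg.samples_per_group), ("control", cfg.samples_per_group)):
                for j in range(n):
                    sample_ids.append(f"s{si}_{comp}_{grp}{j:02d}")
                    groups.append(grp)
                    comps.append(comp)
                    genders.append("M" if rng.random() < 0.5 else "F")
                    base = 4.0 if grp == "case" else 1.0
                    scores.append(round(float(np.clip(rng.normal(base, 1.0), 0, 6)), 2))
        samples = pd.DataFrame(
            {"group": groups, "gender": genders, "compartment": comps, "score": scores},
            index=pd.Index(sample_ids, name="sample_id"),
        )
        values = baseline[:, None] + rng.normal(0.0, cfg.noise_sd, size=(len(probes), len(sample_ids)))
        case_cols = np.array([g == "case" for g in groups])
        values[np.ix_(planted_mask, case_cols)] -= cfg.effect_size
        matrix = pd.DataFrame(values, index=probes, columns=samples.index)
        studies.append(
            ExpressionStudy(
                name=f"study{si}",
                matrix=matrix,
                samples=samples,
                probe_map=probe_map,
                pa_calls=_pa_from_intensity(matrix),
            )
        )
    return studies


# ---------------------------------------------------------------- compendium

def simulate_sample_compendium(cfg: SimulationConfig) -> SampleCompendium:
    """A single-dataset compendium with a gender-biased high-expression gene.

    Samples are iid Gaussian per probeset; in a random fraction
    (``gender_bias_penetrance``) of the biased gender's samples, the biased
    gene's probesets are shifted up by ``gender_bias_shift`` noise-sd units,
    so the per-sample scan flags mostly that gender.
    """
    if cfg.compendium_size < 30:
        raise ConfigurationError("compendium_size must be >= 30")
    rng = cfg.rng(_COMPENDIUM)
    n = cfg.compendium_size
    n_male = int(round(cfg.compendium_male_fraction * n))
    genders = np.array(["M"] * n_male + ["F"] * (n - n_male))
    rng.shuffle(genders)
    sample_ids = pd.Index([f"gsm{i:04d}" for i in range(n)], name="sample_id")

    n_probes = cfg.compendium_probesets
    gene_probes = [f"cps{i:04d}" for i in range(3)]
    other_probes = [f"cps{i:04d}" for i in range(3, n_probes)]
    probe_map = pd.Series(
        [cfg.gender_biased_gene] * 3
        + [f"CBG{i // 2:04d}" for i in range(len(other_probes))],
        index=pd.Index(gene_probes + other_probes, name="probeset"),
    )
    values = rng.normal(8.0, 1.0, size=(n_probes, n))
    biased = (genders == cfg.biased_gender) & (rng.random(n) < cfg.gender_bias_penetrance)
    values[np.ix_(np.arange(3), biased)] += cfg.gender_bias_shift
    matrix = pd.DataFrame(values, index=probe_map.index, columns=sample_ids)
    attributes = pd.DataFrame({"gender": genders}, index=sample_ids)
    dataset = CompendiumDataset(
        name="healthy_brain_compendium", matrix=matrix,
        attributes=attributes, probe_map=probe_map,
    )
    return SampleCompendium(datasets=[dataset])


# ------------------------------------------------------------------ genotype

def gene_regions(cfg: SimulationConfig, window: int = STRICT_WINDOW) -> list[GeneRegion]:
    """Gene bodies laid out evenly along the synthetic chromosome."""
    regions = []
    for i, gene in enumerate(cfg.planted_down_genes):
        start = 1_000_000 + i * cfg.gene_spacing
        end = start + cfg.gene_length - 1
        if end > cfg.chrom_length:
            raise GenerationError(f"gene {gene} falls outside {cfg.chrom}")
        regions.append(GeneRegion(gene=gene, chrom=cfg.chrom, start=start, end=end,
                                  window=window))
    return regions


def _subset_mask(subjects: pd.DataFrame, subset: str) -> np.ndarray:
    gender, apoe = subset[0], subset[1]
    mask = (subjects["gender"] == gender).to_numpy()
    want = "carrier" if apoe == "+" else "non-carrier"
    return mask & (subjects["apoe4"] == want).to_numpy()


def _tune_intercept(offsets: np.ndarray, target: float) -> float:
    """Bisection for the logistic intercept hitting the target case fraction."""
    lo, hi = -15.0, 15.0
    for _ in range(200):
        mid = (lo + hi) / 2.0
        if float(expit(mid + offsets).mean()) < target:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2.0


def simulate_genotype_studies(cfg: SimulationConfig) -> list[GenotypeStudy]:
    """Case/control SNP cohorts with one subset-specific planted risk SNP.

    Genotypes are mutually independent draws under Hardy-Weinberg at
    per-SNP MAFs ~ U(``maf_range``); the planted SNP (MAF ``target_maf``)
    sits inside the body of ``target_gene`` and multiplies the odds of
    disease by ``risk_or`` per alt allele, but only for subjects in
    ``target_subset`` — elsewhere its odds ratio is 1.  Gender and APOE4
    carrier status are assigned independently.

    Each cohort is collected retrospectively, the way case/control cohorts
    are in practice: a source population is simulated with disease status
    drawn from the logistic model (intercept tuned by bisection to
    ``disease_prevalence``), and exactly ``cases_per_study`` cases and
    ``controls_per_study`` controls are sampled from it.
    """
    rng = cfg.rng(_GENO)
    regions = {r.gene: r for r in gene_regions(cfg)}
    if cfg.target_gene not in regions:
        raise GenerationError(f"target gene {cfg.target_gene!r} has no region")
    target_region = regions[cfg.target_gene]
    n_keep = cfg.cases_per_study + cfg.controls_per_study
    # source population sized so both groups are almost surely filled
    pool_n = int(
        2.0 * max(cfg.cases_per_study / cfg.disease_prevalence,
                  cfg.controls_per_study / (1.0 - cfg.disease_prevalence))
    )
    studies = []
    for k in range(cfg.n_snp_studies):
        gender = np.where(rng.random(pool_n) < 0.5, "M", "F")
        apoe4 = np.where(rng.random(pool_n) < cfg.apoe4_frequency, "carrier", "non-carrier")
        pool = pd.DataFrame({"gender": gender, "apoe4": apoe4})

        # positions: background SNPs anywhere, plus the planted SNP mid-gene
        n_bg = cfg.snps_per_study - 1
        positions = rng.integers(1, cfg.chrom_length + 1, size=n_bg)
        target_pos = target_region.start + cfg.gene_length // 2
        positions = np.append(positions, target_pos)
        order = np.argsort(positions, kind="stable")
        positions = positions[order]
        target_row = int(np.where(order == n_bg)[0][0])
        mafs = rng.uniform(*cfg.maf_range, size=cfg.snps_per_study)
        mafs[target_row] = cfg.target_maf
        snp_ids = [f"s{k}_rs{i:05d}" for i in range(cfg.snps_per_study)]
        snp_ids[target_row] = f"s{k}_rs_target"
        snps = pd.DataFrame(
            {"chrom": cfg.chrom, "pos": positions.astype(int), "ref": "A", "alt": "G"},
            index=pd.Index(snp_ids, name="snp_id"),
        )
        genotypes = rng.binomial(2, mafs[:, None], size=(cfg.snps_per_study, pool_n)).astype(float)

        in_subset = _subset_mask(pool, cfg.target_subset)
        offsets = np.log(cfg.risk_or) * genotypes[target_row] * in_subset
        b0 = _tune_intercept(offsets, cfg.disease_prevalence)
        is_case = rng.random(pool_n) < expit(b0 + offsets)
        case_pool = np.flatnonzero(is_case)
        control_pool = np.flatnonzero(~is_case)
        if len(case_pool) < cfg.cases_per_study or len(control_pool) < cfg.controls_per_study:
            raise GenerationError(
                f"study {k}: source population too small for requested cohort"
            )
        chosen = np.concatenate(
            [
                rng.choice(case_pool, size=cfg.cases_per_study, replace=False),
                rng.choice(control_pool, size=cfg.controls_per_study, replace=False),
            ]
        )
        subject_ids = pd.Index([f"s{k}_subj{i:04d}" for i in range(n_keep)], name="subject_id")
        subjects = pool.iloc[chosen].set_index(subject_ids)
        subjects.insert(
            0, "status",
            ["case"] * cfg.cases_per_study + ["control"] * cfg.controls_per_study,
        )
        studies.append(
            GenotypeStudy(
                name=f"snp_study{k}",
                subjects=subjects,
                snps=snps,
                genotypes=pd.DataFrame(genotypes[:, chosen], index=snps.index,
                                       columns=subject_ids),
            )
        )
    return studies


# ------------------------------------------------------------------ profiles

def simulate_compound_profiles(cfg: SimulationConfig) -> ProfileSet:
    """Compound-treatment profiles; planted compounds elevate the target gene.

    Profiles are iid standard Gaussian vectors (vehicle-normalized
    log-ratios).  Each planted compound is run once in every configured cell
    line (so it recurs across profiles), with the target gene's probesets
    shifted up by ``compound_shift`` so they land in the top quantile.
    """
    if cfg.n_profiles < 10:
        raise ConfigurationError("n_profiles must be >= 10")
    rng = cfg.rng(_PROFILES)
    n_probes = cfg.profile_probesets
    gene_probes = [f"pps{i:04d}" for i in range(3)]
    other = [f"pps{i:04d}" for i in range(3, n_probes)]
    probe_map = pd.Series(
        [cfg.compound_target_gene] * 3 + [f"PBG{i // 2:04d}" for i in range(len(other))],
        index=pd.Index(gene_probes + other, name="probeset"),
    )
    planted_rows = [(c, cl) for c in cfg.planted_compounds for cl in cfg.cell_lines]
    n_null = cfg.n_profiles - len(planted_rows)
    if n_null < 0:
        raise ConfigurationError("n_profiles too small for planted compounds")
    meta_rows = []
    for i, (compound, cell_line) in enumerate(planted_rows):
        meta_rows.append((f"profile{i:04d}", compound, cell_line, "build01"))
    for j in range(n_null):
        i = len(planted_rows) + j
        meta_rows.append(
            (f"profile{i:04d}", f"compound-{j // 2:03d}",
             cfg.cell_lines[j % len(cfg.cell_lines)],
             "build01" if j % 2 == 0 else "build02")
        )
    meta = pd.DataFrame(
        meta_rows, columns=["profile_id", "compound", "cell_line", "build"]
    ).set_index("profile_id")
    values = rng.normal(0.0, 1.0, size=(n_probes, cfg.n_profiles))
    values[:3, : len(planted_rows)] += cfg.compound_shift
    frame = pd.DataFrame(values, index=probe_map.index, columns=meta.index)
    return ProfileSet(values=frame, meta=meta, probe_map=probe_map)


# -------------------------------------------------------------------- tissue

def simulate_tissue_matrix(cfg: SimulationConfig,
                           n_brain: int = 6, n_other: int = 18) -> tuple[pd.DataFrame, pd.Series]:
    """Gene x tissue panel in which the planted genes are brain-enriched.

    Returns ``(matrix, brain_flags)``.  Convenience input for the
    tissue-profile stage; planted genes get a 3-unit shift in brain tissues
    over a N(6, 1) background.
    """
    rng = cfg.rng(_TISSUE)
    tissues = [f"brain_{i}" for i in range(n_brain)] + [f"tissue_{i}" for i in range(n_other)]
    flags = pd.Series([True] * n_brain + [False] * n_other, index=pd.Index(tissues, name="tissue"))
    genes = list(cfg.planted_down_genes) + [f"HK{i:03d}" for i in range(12)]
    values = rng.normal(6.0, 1.0, size=(len(genes), len(tissues)))
    values[: len(cfg.planted_down_genes), :n_brain] += 3.0
    matrix = pd.DataFrame(values, index=pd.Index(genes, name="gene"), columns=flags.index)
    return matrix, flags


@dataclass
class SyntheticTruth:
    """Ground truth of one simulated collection, for recovery checks."""

    planted_down_genes: tuple[str, ...]
    target_gene: str
    target_subset: str
    biased_gender: str
    gender_biased_gene: str
    planted_compounds: tuple[str, ...] = field(default_factory=tuple)


def truth_of(cfg: SimulationConfig) -> SyntheticTruth:
    return SyntheticTruth(
        planted_down_genes=cfg.planted_down_genes,
        target_gene=cfg.target_gene,
        target_subset=cfg.target_subset,
        biased_gender=cfg.biased_gender,
        gender_biased_gene=cfg.gender_biased_gene,
        planted_compounds=cfg.planted_compounds,
    )
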