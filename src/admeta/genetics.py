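"""Gene-windowed, stratified case/control SNP association with replication.

Rather than a genome-wide scan, association testing is restricted to windows
around a short list of expression-derived candidate genes (200 kb strict,
1 Mb lenient), which justifies a relaxed per-SNP threshold (5e-4 strict,
1e-2 lenient) in place of genome-wide correction.  Each windowed SNP gets a
1-df Pearson chi-square on the 2x2 allele-count table (the classic allelic
test, no continuity correction), computed within patient strata defined by
gender and APOE4 carrier status.  A gene-stratum pair is *flagged* when at
least ``min_studies`` of the available cohorts hold a below-threshold SNP in
the gene's window — a replication criterion that is the module's main
output.  A log2 genotype "propensity" statistic summarizes per-genotype-class
disease preference for visualization.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

STRICT_WINDOW = 200_000
LENIENT_WINDOW = 1_000_000
STRICT_P = 5e-4
LENIENT_P = 1e-2


class GenerationError(ValueError):
    pass


@dataclass
class GenotypeStudy:
    """A case/control SNP cohort.

    ``subjects``: one row per subject (index = subject id) with columns
    ``status`` (case/control), ``gender`` (M/F) and ``apoe4``
    (carrier/non-carrier).  ``snps``: one row per SNP (index = SNP id) with
    ``chrom``, ``pos`` (1-based), ``ref``, ``alt``.  ``genotypes``: SNP x
    subject alt-allele counts coded 0/1/2, NaN for missing.
    """

    name: str
    subjects: pd.DataFrame
    snps: pd.DataFrame
    genotypes: pd.DataFrame

    def __post_init__(self) -> None:
        if self.subjects.index.has_duplicates:
            raise ValueError(f"study {self.name!r}: duplicate subject ids")
        if not self.genotypes.columns.equals(self.subjects.index):
            raise ValueError(f"study {self.name!r}: genotype columns != subject ids")
        if not self.genotypes.index.equals(self.snps.index):
            raise ValueError(f"study {self.name!r}: genotype rows != SNP ids")
        g = self.genotypes.to_numpy(dtype=float)
        valid = np.isnan(g) | np.isin(g, (0.0, 1.0, 2.0))
        if not valid.all():
            raise ValueError(f"study {self.name!r}: genotype codes outside {{0,1,2,missing}}")
        for chrom, grp in self.snps.groupby("chrom", sort=False):
            if not grp["pos"].is_monotonic_increasing:
                raise ValueError(f"study {self.name!r}: positions not increasing on {chrom}")


@dataclass(frozen=True)
class GeneRegion:
    """A gene body (1-based, inclusive) plus the window D added on each side."""

    gene: str
    chrom: str
    start: int
    end: int
    window: int = STRICT_WINDOW

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"{self.gene}: start > end")
        if self.window < 0:
            raise ValueError(f"{self.gene}: negative window")


@dataclass(frozen=True)
class StratumSpec:
    """Gender x APOE4 filter; 'any' leaves the axis unrestricted."""

    gender: str = "any"  # M | F | any
    apoe4: str = "any"  # carrier | non-carrier | any

    def __post_init__(self) -> None:
        if self.gender not in ("M", "F", "any"):
            raise ValueError(f"bad gender filter {self.gender!r}")
        if self.apoe4 not in ("carrier", "non-carrier", "any"):
            raise ValueError(f"bad apoe4 filter {self.apoe4!r}")

    @property
    def label(self) -> str:
        g = {"M": "M", "F": "F", "any": "all"}[self.gender]
        a = {"carrier": "APOE4+", "non-carrier": "APOE4-", "any": "all"}[self.apoe4]
        return f"{g}/{a}"


#: The nine canonical strata: {M, F, any} x {carrier, non-carrier, any}.
CANONICAL_STRATA: tuple[StratumSpec, ...] = tuple(
    StratumSpec(gender=g, apoe4=a)
    for g in ("any", "F", "M")
    for a in ("any", "carrier", "non-carrier")
)


@dataclass
class AssociationRow:
    snp_id: str
    stratum: str
    case_alt: int
    case_ref: int
    control_alt: int
    control_ref: int
    chi2: float
    p: float
    odds_ratio: float  # NaN when undefined (monomorphic SNP)


def stratify(study: GenotypeStudy, spec: StratumSpec) -> GenotypeStudy:
    """Subset a cohort to one gender x APOE4 stratum."""
    keep = pd.Series(True, index=study.subjects.index)
    if spec.gender != "any":
        keep &= study.subjects["gender"] == spec.gender
    if spec.apoe4 != "any":
        keep &= study.subjects["apoe4"] == spec.apoe4
    ids = study.subjects.index[keep]
    if len(ids) == 0:
        logger.warning("study %s: stratum %s is empty", study.name, spec.label)
    return replace(
        study,
        subjects=study.subjects.loc[ids],
        genotypes=study.genotypes[ids],
    )


def _chi2_2x2(a: float, b: float, c: float, d: float) -> float:
    """Pearson chi-square (1 df, no continuity correction) of [[a,b],[c,d]]."""
    n = a + b + c + d
    denom = (a + b) * (c + d) * (a + c) * (b + d)
    if denom == 0:
        return 0.0
    return n * (a * d - b * c) ** 2 / denom


def allelic_test(
    genotypes,
    is_case,
    snp_id: str = "",
    stratum: str = "",
    fisher: bool = False,
) -> AssociationRow:
    """Basic allelic association test on one SNP.

    Builds the 2x2 table of alt/ref *allele* counts (two alleles per subject)
    in cases vs controls over non-missing genotypes, and tests it with the
    1-df Pearson chi-square without continuity correction; ``fisher=True``
    substitutes Fisher's exact test.  The odds ratio is
    (case_alt*control_ref)/(case_ref*control_alt), with a 0.5 pseudocount on
    every cell when any cell is zero.  Monomorphic SNPs return p = 1 and an
    undefined (NaN) odds ratio.
    """
    g = np.asarray(genotypes, dtype=float)
    case_mask = np.asarray(is_case, dtype=bool)
    ok = ~np.isnan(g)
    if not (ok & case_mask).any() or not (ok & ~case_mask).any():
        raise ValueError("need >=1 case and >=1 control with non-missing genotype")
    n_case = int((ok & case_mask).sum())
    n_ctrl = int((ok & ~case_mask).sum())
    case_alt = int(g[ok & case_mask].sum())
    ctrl_alt = int(g[ok & ~case_mask].sum())
    case_ref = 2 * n_case - case_alt
    ctrl_ref = 2 * n_ctrl - ctrl_alt
    total_alt, total_ref = case_alt + ctrl_alt, case_ref + ctrl_ref
    if total_alt == 0 or total_ref == 0:  # monomorphic
        return AssociationRow(snp_id, stratum, case_alt, case_ref, ctrl_alt, ctrl_ref,
                              0.0, 1.0, float("nan"))
    if fisher:
        _, p = stats.fisher_exact([[case_alt, case_ref], [ctrl_alt, ctrl_ref]])
        chi2 = _chi2_2x2(case_alt, case_ref, ctrl_alt, ctrl_ref)
    else:
        chi2 = _chi2_2x2(case_alt, case_ref, ctrl_alt, ctrl_ref)
        p = float(stats.chi2.sf(chi2, df=1))
    cells = np.array([case_alt, case_ref, ctrl_alt, ctrl_ref], dtype=float)
    if (cells == 0).any():
        cells = cells + 0.5
    odds = (cells[0] * cells[3]) / (cells[1] * cells[2])
    return AssociationRow(snp_id, stratum, case_alt, case_ref, ctrl_alt, ctrl_ref,
                          float(chi2), float(min(p, 1.0)), float(odds))


def window_select(region: GeneRegion, snps: pd.DataFrame) -> pd.Index:
    """SNP ids with start - D <= pos <= end + D on the region's chromosome
    (both boundaries inclusive)."""
    lo = region.start - region.window
    hi = region.end + region.window
    mask = (snps["chrom"] == region.chrom) & (snps["pos"] >= lo) & (snps["pos"] <= hi)
    return snps.index[mask]


def region_scan(
    study: GenotypeStudy,
    regions: list[GeneRegion],
    strata: tuple[StratumSpec, ...] = CANONICAL_STRATA,
    p_threshold: float = STRICT_P,
    fisher: bool = False,
    bh_within_window: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Allelic tests for every windowed SNP in every requested stratum.

    Significance is raw p < ``p_threshold`` with no multiple-testing
    correction: restricting SNPs to candidate-gene windows already curbs
    false positives, which is what licenses the relaxed threshold.
    ``bh_within_window=True`` switches to BH-adjusted p within each
    gene-window x stratum for sensitivity analysis.

    Returns ``(rows, best)``: per-SNP association rows, and per (gene,
    stratum) the best p in the window (NaN when the stratum was empty or the
    window held no SNP).
    """
    if not regions:
        raise ValueError("no regions supplied")
    rows: list[dict] = []
    best_records: list[dict] = []
    for spec in strata:
        sub = stratify(study, spec)
        status = sub.subjects["status"] == "case"
        testable = status.any() and (~status).any()
        for region in regions:
            snp_ids = window_select(region, sub.snps)
            if not testable or len(snp_ids) == 0:
                best_records.append(
                    {"gene": region.gene, "stratum": spec.label,
                     "best_p": np.nan, "n_snps": int(len(snp_ids)),
                     "tested": bool(testable and len(snp_ids))}
                )
                continue
            region_rows = []
            for snp in snp_ids:
                row = allelic_test(
                    sub.genotypes.loc[snp], status, snp_id=snp,
                    stratum=spec.label, fisher=fisher,
                )
                region_rows.append(
                    {"gene": region.gene, "stratum": spec.label, "snp_id": row.snp_id,
                     "pos": int(sub.snps.at[snp, "pos"]),
                     "case_alt": row.case_alt, "case_ref": row.case_ref,
                     "control_alt": row.control_alt, "control_ref": row.control_ref,
                     "chi2": row.chi2, "p": row.p, "odds_ratio": row.odds_ratio}
                )
            frame = pd.DataFrame(region_rows)
            if bh_within_window:
                from admeta.scan import bh_adjust

                frame["p_effective"] = bh_adjust(frame["p"].to_numpy())
            else:
                frame["p_effective"] = frame["p"]
            frame["significant"] = frame["p_effective"] < p_threshold
            rows.append(frame)
            best_records.append(
                {"gene": region.gene, "stratum": spec.label,
                 "best_p": float(frame["p_effective"].min()),
                 "n_snps": int(len(frame)), "tested": True}
            )
    all_rows = (
        pd.concat(rows, ignore_index=True)
        if rows
        else pd.DataFrame(
            columns=["gene", "stratum", "snp_id", "pos", "case_alt", "case_ref",
                     "control_alt", "control_ref", "chi2", "p", "odds_ratio",
                     "p_effective", "significant"]
        )
    )
    best = pd.DataFrame.from_records(best_records)
    return all_rows, best


def replication_filter(
    best_tables: dict[str, pd.DataFrame],
    p_threshold: float = STRICT_P,
    min_studies: int = 2,
) -> pd.DataFrame:
    """Cross-study replication: flag gene-strata significant in >= ``min_studies``.

    ``best_tables`` maps study name to a ``region_scan`` best-p table.  A
    study supports a (gene, stratum) when its window there holds at least one
    SNP with p below ``p_threshold``.  Returns one row per (gene, stratum)
    with per-study best p, the supporting-study count and the flag.
    """
    if len(best_tables) < 2:
        raise ValueError("replication needs >=2 studies")
    pieces = []
    for name, best in best_tables.items():
        piece = best.set_index(["gene", "stratum"])["best_p"].rename(name)
        pieces.append(piece)
    wide = pd.concat(pieces, axis=1)
    sig = wide < p_threshold  # NaN (untested) compares False
    out = wide.copy()
    out["n_significant_studies"] = sig.sum(axis=1).astype(int)
    out["flagged"] = out["n_significant_studies"] >= min_studies
    out["p_threshold"] = p_threshold
    out["min_studies"] = min_studies
    return out.reset_index()


def propensity(
    case_counts,
    control_counts,
    pseudocount: float = 0.5,
    log_scale: bool = True,
) -> pd.DataFrame:
    """Genotype propensity: log2 ratio of case to control class fractions.

    For each genotype class i (0/1/2 alt-allele copies),
    ``propensity_i = log2[(CASE_i/CASE) / (CONTROL_i/CONTROL)]`` where CASE_i
    is the number of cases with class i and CASE the case total.  Positive
    values mark disease risk, negative values protection, and swapping case
    and control labels negates every value.  When any class count is zero the
    pseudocount is added to *all* class counts (totals are recomputed from the
    adjusted counts so the antisymmetry is preserved); classes absent from
    both groups are reported as NaN rather than +/-inf.
    ``log_scale=False`` returns the linear ratio instead.
    """
    case = np.asarray(case_counts, dtype=float)
    ctrl = np.asarray(control_counts, dtype=float)
    if case.shape != (3,) or ctrl.shape != (3,):
        raise ValueError("expected per-class counts for genotype classes 0, 1, 2")
    if (case < 0).any() or (ctrl < 0).any():
        raise ValueError("negative class counts")
    if case.sum() == 0 or ctrl.sum() == 0:
        raise ValueError("need at least one case and one control")
    absent = (case == 0) & (ctrl == 0)
    adj_case, adj_ctrl = case.copy(), ctrl.copy()
    if (case == 0).any() or (ctrl == 0).any():
        adj_case = adj_case + pseudocount
        adj_ctrl = adj_ctrl + pseudocount
    ratio = (adj_case / adj_case.sum()) / (adj_ctrl / adj_ctrl.sum())
    values = np.log2(ratio) if log_scale else ratio
    values = np.where(absent, np.nan, values)
    return pd.DataFrame(
        {
            "genotype_class": [0, 1, 2],
            "case_count": case.astype(int),
            "control_count": ctrl.astype(int),
            "propensity": values,
        }
    )


def genotype_propensity(
    genotypes,
    is_case,
    pseudocount: float = 0.5,
    log_scale: bool = True,
) -> pd.DataFrame:
    """Convenience wrapper: class counts from one SNP's coded genotypes."""
    g = np.asarray(genotypes, dtype=float)
    case_mask = np.asarray(is_case, dtype=bool)
    ok = ~np.isnan(g)
    case = [int(((g == i) & case_mask & ok).sum()) for i in (0, 1, 2)]
    ctrl = [int(((g == i) & ~case_mask & ok).sum()) for i in (0, 1, 2)]
    return propensity(case, ctrl, pseudocount=pseudocount, log_scale=log_scale)
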