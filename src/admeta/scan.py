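"""Per-sample rank-enrichment scan of an expression compendium.

For a gene of interest, each sample in a compendium dataset is tested for
whether the gene's probesets sit unusually high in that sample's expression
distribution (a one-sided rank-sum test of the gene's probesets against all
remaining probesets in the same sample).  P-values are Benjamini-Hochberg
corrected *within* each dataset, and samples passing the adjusted threshold
are the "enriched" set.  Categorical sample attributes (gender, tissue, ...)
are then tested for over-representation among the enriched samples with an
upper-tail hypergeometric test, skipped when the enriched set is too small
for the count to be meaningful.

The rank statistic here is shared with the compound-profile search
(:mod:`admeta.compounds`): a treatment profile is just another "sample".
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

#: Minimum number of enriched samples for the attribute test to be reported.
DEFAULT_MIN_ENRICHED = 15


@dataclass
class CompendiumDataset:
    """One dataset of a compendium: an expression matrix plus sample attributes.

    Parameters
    ----------
    name:
        Dataset identifier, unique within the compendium.
    matrix:
        Probeset-by-sample expression values (any monotone scale; the scan is
        rank-based within each sample).
    attributes:
        One row per sample (index = sample id), categorical columns such as
        ``gender``.
    probe_map:
        Probeset id -> gene symbol (many-to-one).
    """

    name: str
    matrix: pd.DataFrame
    attributes: pd.DataFrame
    probe_map: pd.Series

    def __post_init__(self) -> None:
        if self.matrix.columns.has_duplicates:
            raise ValueError(f"dataset {self.name!r}: duplicate sample ids")
        missing = self.matrix.columns.difference(self.attributes.index)
        if len(missing):
            raise ValueError(
                f"dataset {self.name!r}: samples without attribute rows: "
                f"{list(missing[:5])}"
            )

    def probesets_for(self, gene: str) -> list[str]:
        hits = self.probe_map.index[self.probe_map == gene]
        return [p for p in hits if p in self.matrix.index]


@dataclass
class SampleCompendium:
    datasets: list[CompendiumDataset] = field(default_factory=list)

    def __post_init__(self) -> None:
        names = [d.name for d in self.datasets]
        if len(set(names)) != len(names):
            raise ValueError("duplicate dataset names in compendium")


@dataclass(frozen=True)
class EnrichmentCount:
    """Counts feeding the hypergeometric attribute-enrichment test.

    ``N`` samples in the dataset, ``K`` of which carry the attribute value;
    ``m`` samples were flagged as enriched, ``k`` of those carry the value.
    """

    N: int
    K: int
    m: int
    k: int
    min_m: int = DEFAULT_MIN_ENRICHED

    def __post_init__(self) -> None:
        if not (0 <= self.K <= self.N and 0 <= self.m <= self.N):
            raise ValueError(f"inconsistent counts: {self}")
        if not 0 <= self.k <= min(self.m, self.K):
            raise ValueError(f"k must satisfy 0 <= k <= min(m, K): {self}")


def rank_enrichment_p(
    gene_values,
    other_values,
    alternative: str = "greater",
    mode: str = "ranksum",
) -> float:
    """One-sided p-value that a gene's probesets rank high within a sample.

    The default statistic is a two-sample Wilcoxon rank-sum (Mann-Whitney) of
    the gene's ``k`` probeset values against the ``N - k`` remaining probeset
    values of the same sample.  The null is exchangeability of ranks, so for a
    single probeset that is the sample maximum the p-value is exactly ``1/N``.

    The exact null distribution is used whenever the data are tie-free and
    small enough to enumerate cheaply (``k <= 2`` at any ``N <= 1000``, or any
    ``k`` at ``N <= 50``); otherwise the tie-corrected normal approximation
    with continuity correction is used.

    ``mode="signed_rank"`` tests the gene's values against the sample median
    with a one-sample signed-rank test instead; note its one-sided p cannot
    fall below ``2**-k``, so it is uninformative for genes with few probesets
    and exists only for fidelity audits.
    """
    gene_values = np.asarray(gene_values, dtype=float)
    other_values = np.asarray(other_values, dtype=float)
    k, n_other = gene_values.size, other_values.size
    if k < 1:
        raise ValueError("need at least one gene value")
    pooled = np.concatenate([gene_values, other_values])
    if np.ptp(pooled) == 0:
        return 1.0

    if mode == "signed_rank":
        center = np.median(pooled)
        diffs = gene_values - center
        if np.all(diffs == 0):
            return 1.0
        return float(
            stats.wilcoxon(diffs, alternative=alternative, zero_method="wilcox").pvalue
        )
    if mode != "ranksum":
        raise ValueError(f"unknown mode {mode!r}")

    n_total = k + n_other
    tie_free = np.unique(pooled).size == n_total
    exact_ok = tie_free and ((k <= 2 and n_total <= 1000) or n_total <= 50)
    method = "exact" if exact_ok else "asymptotic"
    res = stats.mannwhitneyu(
        gene_values, other_values, alternative=alternative, method=method
    )
    return float(min(res.pvalue, 1.0))


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


def scan_dataset(
    dataset: CompendiumDataset,
    gene: str,
    alpha: float = 0.05,
    mode: str = "ranksum",
) -> pd.DataFrame | None:
    """Scan every sample of one dataset for high expression of ``gene``.

    Returns a frame indexed by sample id with columns ``raw_p``, ``adj_p``
    (BH within this dataset) and ``enriched`` (adjusted p < ``alpha``), or
    ``None`` when the gene has no probeset in the dataset.
    """
    probes = dataset.probesets_for(gene)
    if not probes:
        logger.info("dataset %s: gene %s has no probesets, skipped", dataset.name, gene)
        return None
    gene_rows = dataset.matrix.loc[probes]
    other_rows = dataset.matrix.drop(index=probes)
    raw = np.array(
        [
            rank_enrichment_p(
                gene_rows[s].to_numpy(), other_rows[s].to_numpy(), mode=mode
            )
            for s in dataset.matrix.columns
        ]
    )
    adj = bh_adjust(raw)
    return pd.DataFrame(
        {"raw_p": raw, "adj_p": adj, "enriched": adj < alpha},
        index=dataset.matrix.columns.rename("sample_id"),
    )


def attribute_enrichment(count: EnrichmentCount) -> dict:
    """Upper-tail hypergeometric test of an attribute among enriched samples.

    Returns ``{"status": "ok", "p": P(X >= k)}`` with X hypergeometric
    (N, K, m), or ``{"status": "skipped", ...}`` when fewer than ``min_m``
    samples were enriched — with so few flags the attribute split carries
    little evidence either way.
    """
    if count.m < count.min_m:
        return {"status": "skipped", "p": np.nan, "reason": f"m={count.m} < {count.min_m}"}
    p = float(stats.hypergeom.sf(count.k - 1, count.N, count.K, count.m))
    return {"status": "ok", "p": p, "reason": ""}


def scan_compendium(
    compendium: SampleCompendium,
    gene: str,
    attribute: str,
    values: list[str] | None = None,
    alpha: float = 0.05,
    min_m: int = DEFAULT_MIN_ENRICHED,
) -> pd.DataFrame:
    """Run the scan across a compendium and test one attribute per dataset.

    One row per (dataset, attribute value); rows are sorted by p-value with
    skipped rows retained at the end.  Datasets lacking the gene or the
    attribute column contribute no rows.
    """
    records = []
    for ds in compendium.datasets:
        if attribute not in ds.attributes.columns:
            logger.info("dataset %s: attribute %r absent, skipped", ds.name, attribute)
            continue
        result = scan_dataset(ds, gene, alpha=alpha)
        if result is None:
            continue
        attr = ds.attributes.loc[result.index, attribute]
        enriched = result["enriched"]
        vals = values if values is not None else sorted(attr.dropna().unique())
        for v in vals:
            has_value = attr == v
            count = EnrichmentCount(
                N=int(len(result)),
                K=int(has_value.sum()),
                m=int(enriched.sum()),
                k=int((enriched & has_value).sum()),
                min_m=min_m,
            )
            res = attribute_enrichment(count)
            records.append(
                {
                    "dataset": ds.name,
                    "attribute_value": v,
                    "N": count.N,
                    "K": count.K,
                    "m": count.m,
                    "k": count.k,
                    "p": res["p"],
                    "status": res["status"],
                    "reason": res["reason"],
                }
            )
    table = pd.DataFrame.from_records(
        records,
        columns=[
            "dataset", "attribute_value", "N", "K", "m", "k", "p", "status", "reason",
        ],
    )
    return table.sort_values(["p", "dataset", "attribute_value"], na_position="last").reset_index(
        drop=True
    )
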