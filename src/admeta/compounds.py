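"""Connectivity-Map-style search for compounds elevating a gene of interest.

Each treatment profile (one expression vector from cultured cells treated
with one compound) is tested for whether the gene's probesets rank unusually
high within the profile, using the same rank-enrichment statistic as the
compendium scan.  P-values are BH-corrected jointly across all loaded
profiles (builds are pooled), and significant profiles are collapsed to
unique compounds, since the same compound recurs across cell lines and
repeated experiments.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from admeta.scan import bh_adjust, rank_enrichment_p

logger = logging.getLogger(__name__)


@dataclass
class ProfileSet:
    """Compound-treatment expression profiles plus their metadata.

    ``values``: probeset x profile matrix (already vehicle-normalized;
    raw intensities or log-ratios — the test is rank-based within each
    profile).  ``meta``: one row per profile (index = profile id) with
    columns ``compound``, ``cell_line`` and ``build``.  ``probe_map``:
    probeset -> gene symbol.
    """

    values: pd.DataFrame
    meta: pd.DataFrame
    probe_map: pd.Series

    def __post_init__(self) -> None:
        if self.values.columns.has_duplicates:
            raise ValueError("duplicate profile ids")
        missing = self.values.columns.difference(self.meta.index)
        if len(missing):
            raise ValueError(f"profiles without metadata: {list(missing[:5])}")
        if (self.meta["compound"].astype(str).str.len() == 0).any():
            raise ValueError("empty compound names")

    def probesets_for(self, gene: str) -> list[str]:
        hits = self.probe_map.index[self.probe_map == gene]
        return [p for p in hits if p in self.values.index]


def compound_scan(profiles: ProfileSet, gene: str, alpha: float = 0.05) -> pd.DataFrame:
    """Profiles in which ``gene`` is significantly elevated, at FDR ``alpha``.

    One-sided ("greater") rank-enrichment p per profile, BH across all
    profiles jointly; rows with adjusted p < ``alpha`` are returned sorted by
    raw p.  Raises ``KeyError`` when the gene is absent from the probe map.
    """
    probes = profiles.probesets_for(gene)
    if not probes:
        raise KeyError(f"gene {gene!r} has no probesets in this profile set")
    gene_rows = profiles.values.loc[probes]
    other_rows = profiles.values.drop(index=probes)
    raw = np.array(
        [
            rank_enrichment_p(gene_rows[c].to_numpy(), other_rows[c].to_numpy())
            for c in profiles.values.columns
        ]
    )
    table = profiles.meta.loc[profiles.values.columns, ["compound", "cell_line", "build"]].copy()
    table["raw_p"] = raw
    table["adj_p"] = bh_adjust(raw)
    table.index.name = "profile_id"
    sig = table[table["adj_p"] < alpha].sort_values(["raw_p", "compound"])
    logger.info("compound scan for %s: %d/%d profiles significant", gene, len(sig), len(table))
    return sig.reset_index()


def collapse_compounds(significant: pd.DataFrame) -> pd.DataFrame:
    """Collapse significant profiles to unique compounds.

    Groups by compound name and reports the best (minimum) raw p, its
    adjusted p, and the number of supporting profiles, sorted by best p.
    Idempotent and order-invariant.
    """
    if significant.empty:
        return pd.DataFrame(columns=["compound", "p_val", "adj_p_val", "n_profiles"])
    # allow re-collapsing an already collapsed table
    raw_col = "raw_p" if "raw_p" in significant.columns else "p_val"
    adj_col = "adj_p" if "adj_p" in significant.columns else "adj_p_val"
    n_col = significant["n_profiles"] if "n_profiles" in significant.columns else 1
    work = significant.assign(_n=n_col)
    rows = []
    for compound, grp in work.groupby("compound", sort=False):
        best = grp.loc[grp[raw_col].idxmin()]
        rows.append(
            {
                "compound": compound,
                "p_val": float(best[raw_col]),
                "adj_p_val": float(best[adj_col]),
                "n_profiles": int(grp["_n"].sum()),
            }
        )
    out = pd.DataFrame(rows).sort_values(["p_val", "compound"]).reset_index(drop=True)
    return out
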