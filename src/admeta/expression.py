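"""Per-study differential expression and the cross-study intersection.

Each case/control study is analyzed independently: a two-group test per
probeset (Welch t by default, with an optional empirical-Bayes
variance-moderated mode), Benjamini-Hochberg correction at FDR 0.05, QC on
array control probesets, optional Presence/Absence filtering where detection
calls exist, and mapping of surviving probesets to gene symbols.  The gene
lists are then intersected across studies, and the intersection is confirmed
in a held-out study.  The stringency of the intersection — a gene must be
significant, in the same direction, in every study — is the point: it trades
sensitivity for a list unambiguously associated with the disease.
"""

from __future__ import annotations

import logging
from collections.abc import Callable, Mapping, Sequence
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats

from admeta.scan import bh_adjust

logger = logging.getLogger(__name__)

PA_CODES = {"A": 0, "M": 1, "P": 2}
#: Name prefix of Affymetrix spike-in/control probesets targeted by the QC rule.
CONTROL_PREFIX = "AFFX-"


class ContrastError(ValueError):
    """A contrast group is empty or too small to test."""


@dataclass(frozen=True)
class Contrast:
    """Sample ids for the two groups of a two-group comparison."""

    case_ids: tuple[str, ...]
    control_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        if set(self.case_ids) & set(self.control_ids):
            raise ContrastError("case and control groups overlap")


@dataclass
class ExpressionStudy:
    """A normalized probeset-by-sample log-expression matrix with metadata.

    ``samples`` has one row per sample (index = sample id) with columns
    ``group`` (case/control), ``gender`` (M/F/unknown), ``compartment`` and an
    optional numeric ``score`` (disease-severity covariate).  ``pa_calls``,
    when present, shares the matrix's axes exactly and holds detection codes
    (A/M/P or 0/1/2).  ``probe_map`` maps probeset id to gene symbol,
    many-to-one.
    """

    name: str
    matrix: pd.DataFrame
    samples: pd.DataFrame
    probe_map: pd.Series
    pa_calls: pd.DataFrame | None = None
    control_prefix: str = CONTROL_PREFIX

    def __post_init__(self) -> None:
        if self.matrix.columns.has_duplicates:
            raise ValueError(f"study {self.name!r}: duplicate sample ids")
        missing = self.matrix.columns.difference(self.samples.index)
        if len(missing):
            raise ValueError(f"study {self.name!r}: samples missing metadata: {list(missing[:5])}")
        if self.pa_calls is not None:
            if not (
                self.pa_calls.index.equals(self.matrix.index)
                and self.pa_calls.columns.equals(self.matrix.columns)
            ):
                raise ValueError(f"study {self.name!r}: pa_calls axes differ from matrix")

    def is_control_probe(self, probeset: str) -> bool:
        return probeset.startswith(self.control_prefix)

    def group_contrast(
        self, compartment: str | None = None, case: str = "case", control: str = "control"
    ) -> Contrast:
        """Contrast of the ``group`` column, optionally within one compartment."""
        meta = self.samples
        if compartment is not None:
            meta = meta[meta["compartment"] == compartment]
        return Contrast(
            case_ids=tuple(meta.index[meta["group"] == case]),
            control_ids=tuple(meta.index[meta["group"] == control]),
        )


@dataclass
class DEResult:
    """Per-probeset differential-expression table for one contrast.

    Columns of ``table`` (indexed by probeset): ``log_fc`` (case minus
    control, log2), ``stat``, ``p_value``, ``adj_p`` (BH over all tested
    probesets), ``direction`` (up/down/none) and ``significant``.
    """

    table: pd.DataFrame
    alpha: float
    n_case: int
    n_control: int

    def significant(self, direction: str | None = None) -> pd.DataFrame:
        sig = self.table[self.table["significant"]]
        if direction is not None:
            sig = sig[sig["direction"] == direction]
        return sig


def _welch(case: np.ndarray, ctrl: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise Welch t statistics and two-sided p; zero-variance rows -> p=1."""
    n1, n2 = case.shape[1], ctrl.shape[1]
    m1, m2 = case.mean(axis=1), ctrl.mean(axis=1)
    v1 = case.var(axis=1, ddof=1)
    v2 = ctrl.var(axis=1, ddof=1)
    se2 = v1 / n1 + v2 / n2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (m1 - m2) / np.sqrt(se2)
        df = se2**2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
    flat = ~np.isfinite(t)
    t[flat] = 0.0
    df[flat] = n1 + n2 - 2
    p = 2.0 * stats.t.sf(np.abs(t), df)
    p[flat] = 1.0
    return t, np.minimum(p, 1.0)


def _invert_trigamma(x: float) -> float:
    # Newton iteration for psi'(y) = x, y > 0 (x > 0).
    y = 0.5 + 1.0 / x
    for _ in range(60):
        tri = special.polygamma(1, y)
        step = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y -= step
        if abs(step) < 1e-10 * y:
            break
    return float(y)


def _moderated(case: np.ndarray, ctrl: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Empirical-Bayes moderated t: per-row pooled variances shrunk toward a
    common prior estimated by method of moments on the log-variances."""
    n1, n2 = case.shape[1], ctrl.shape[1]
    df = n1 + n2 - 2
    m1, m2 = case.mean(axis=1), ctrl.mean(axis=1)
    s2 = (case.var(axis=1, ddof=1) * (n1 - 1) + ctrl.var(axis=1, ddof=1) * (n2 - 1)) / df
    positive = s2 > 0
    if not positive.any():
        return np.zeros(len(s2)), np.ones(len(s2))
    z = np.log(s2[positive])
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    evar = float(np.var(e, ddof=1)) - float(special.polygamma(1, df / 2.0)) if e.size > 1 else 0.0
    if evar > 0:
        d0 = 2.0 * _invert_trigamma(evar)
        s0_sq = float(np.exp(np.mean(e) + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
        s2_post = (d0 * s0_sq + df * s2) / (d0 + df)
        df_total = df + d0
    else:  # variances essentially exchangeable: fully pooled prior
        s0_sq = float(np.exp(np.mean(e)))
        s2_post = np.full_like(s2, s0_sq)
        df_total = np.inf
    se2 = s2_post * (1.0 / n1 + 1.0 / n2)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (m1 - m2) / np.sqrt(se2)
    flat = ~np.isfinite(t)
    t[flat] = 0.0
    if np.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
    p[flat] = 1.0
    return t, np.minimum(p, 1.0)


def run_de(
    study: ExpressionStudy,
    contrast: Contrast,
    alpha: float = 0.05,
    moderated: bool = False,
) -> DEResult:
    """Two-group differential expression over all probesets of a study.

    Log-fold-change is ``mean(case) - mean(control)`` in log2 units; p-values
    are BH-adjusted over every tested probeset; ``significant`` means
    adjusted p < ``alpha``.  Raises :class:`ContrastError` when either group
    has fewer than two samples.
    """
    if len(contrast.case_ids) < 2 or len(contrast.control_ids) < 2:
        raise ContrastError(
            f"need >=2 samples per group, got {len(contrast.case_ids)} case / "
            f"{len(contrast.control_ids)} control"
        )
    case = study.matrix[list(contrast.case_ids)].to_numpy(dtype=float)
    ctrl = study.matrix[list(contrast.control_ids)].to_numpy(dtype=float)
    if not (np.isfinite(case).all() and np.isfinite(ctrl).all()):
        raise ValueError(f"study {study.name!r}: non-finite expression values")
    log_fc = case.mean(axis=1) - ctrl.mean(axis=1)
    stat, p = (_moderated if moderated else _welch)(case, ctrl)
    adj = bh_adjust(p)
    direction = np.where(log_fc < 0, "down", np.where(log_fc > 0, "up", "none"))
    table = pd.DataFrame(
        {
            "log_fc": log_fc,
            "stat": stat,
            "p_value": p,
            "adj_p": adj,
            "direction": direction,
            "significant": adj < alpha,
        },
        index=study.matrix.index.rename("probeset"),
    )
    return DEResult(table=table, alpha=alpha, n_case=case.shape[1], n_control=ctrl.shape[1])


def build_extreme_contrast(scores: pd.Series, n: int) -> Contrast:
    """Extreme-groups contrast: the ``n`` highest scores vs the ``n`` lowest.

    Samples with missing scores are ignored; samples between the two extremes
    are excluded from the contrast.  Ties at either boundary are broken by
    sample id ascending (the lower id wins inclusion).
    """
    scores = scores.dropna()
    if len(scores) < 2 * n:
        raise ContrastError(f"need >= {2 * n} scored samples, have {len(scores)}")
    # stable sort after an id sort: within tied scores, the lower id comes first
    asc = scores.sort_index(kind="stable").sort_values(kind="stable")
    control = tuple(asc.index[:n])
    remaining = asc.drop(index=list(control))
    desc = remaining.sort_index(kind="stable").sort_values(ascending=False, kind="stable")
    case = tuple(desc.index[:n])
    return Contrast(case_ids=case, control_ids=control)


def select_compartment(
    de_by_compartment: Mapping[str, DEResult],
    is_control_probe: Callable[[str], bool],
    exclude: set[str] | None = None,
    alpha: float = 0.05,
    max_control_fraction: float = 0.0025,
    top_n: int = 10,
) -> tuple[str | None, dict]:
    """Pick the compartment with the most significant probesets, after QC.

    A compartment is discarded when array control probesets make up strictly
    more than ``max_control_fraction`` of its significant results, or when any
    control probeset sits among its ``top_n`` smallest raw p-values — either
    pattern suggests technical rather than biological signal.  Ties on the
    significant count are broken by lexicographically smallest label.
    Returns ``(label, qc_report)``; label is ``None`` when every compartment
    is discarded.
    """
    exclude = exclude or set()
    report: dict = {"compartments": {}, "excluded": sorted(exclude)}
    candidates: list[tuple[int, str]] = []
    for label in sorted(de_by_compartment):
        if label in exclude:
            continue
        de = de_by_compartment[label]
        sig = de.table[de.table["adj_p"] < alpha]
        n_sig = int(len(sig))
        ctrl_mask_sig = np.array([is_control_probe(p) for p in sig.index], dtype=bool)
        n_ctrl_sig = int(ctrl_mask_sig.sum())
        frac = n_ctrl_sig / n_sig if n_sig else 0.0
        top = de.table.nsmallest(top_n, "p_value", keep="first").index
        ctrl_in_top = any(is_control_probe(p) for p in top)
        discard = frac > max_control_fraction or ctrl_in_top
        report["compartments"][label] = {
            "n_significant": n_sig,
            "n_control_significant": n_ctrl_sig,
            "control_fraction": frac,
            "control_in_top": bool(ctrl_in_top),
            "discarded": bool(discard),
        }
        if not discard:
            candidates.append((n_sig, label))
    if not candidates:
        logger.warning("all compartments discarded by control-probeset QC: %s", report)
        report["selected"] = None
        return None, report
    # max significant count; ties -> lexicographically smallest label
    best_count = max(cnt for cnt, _ in candidates)
    best_label = min(lbl for cnt, lbl in candidates if cnt == best_count)
    report["selected"] = best_label
    return best_label, report


def presence_filter(
    de: DEResult,
    pa_calls: pd.DataFrame | None,
    contrast: Contrast,
) -> DEResult:
    """Drop significant probesets not reliably detected where they matter.

    For each significant probeset the detection calls (A=0, M=1, P=2) are
    averaged over the samples of the group with the *higher* mean expression
    (controls for a downregulated probeset, cases for an upregulated one);
    the probeset stays significant iff that average is at least marginal
    (>= 1, inclusive).  Studies without detection calls pass through with a
    warning, matching platforms that provide no MM/PM data.
    """
    if pa_calls is None:
        logger.warning("no P/A calls available; presence filter skipped")
        return de
    if pa_calls.dtypes.eq(object).any():
        codes = np.vectorize(lambda v: float(PA_CODES.get(v, v)))(pa_calls.to_numpy(dtype=object))
        calls = pd.DataFrame(codes, index=pa_calls.index, columns=pa_calls.columns)
    else:
        calls = pa_calls.astype(float)
    table = de.table.copy()
    table["pa_mean_high_group"] = np.nan
    sig_idx = table.index[table["significant"]]
    case_cols = [c for c in contrast.case_ids if c in calls.columns]
    ctrl_cols = [c for c in contrast.control_ids if c in calls.columns]
    for probe in sig_idx:
        high_cols = ctrl_cols if table.at[probe, "direction"] == "down" else case_cols
        mean_code = float(calls.loc[probe, high_cols].mean())
        table.at[probe, "pa_mean_high_group"] = mean_code
        if mean_code < 1.0:
            table.at[probe, "significant"] = False
    return DEResult(table=table, alpha=de.alpha, n_case=de.n_case, n_control=de.n_control)


@dataclass
class GeneSets:
    """Per-direction gene sets derived from one study's filtered DE result."""

    down: set[str] = field(default_factory=set)
    up: set[str] = field(default_factory=set)
    ambiguous: set[str] = field(default_factory=set)
    n_unmapped: int = 0


def map_to_genes(de: DEResult, probe_map: pd.Series) -> GeneSets:
    """Collapse probeset calls to gene symbols, per direction.

    A gene enters the down set when *any* of its probesets is significantly
    down (and analogously up); genes with probesets significant in both
    directions land in both sets and are flagged as ambiguous.
    """
    sets = GeneSets()
    sig = de.table[de.table["significant"]]
    unmapped = sig.index.difference(probe_map.index)
    sets.n_unmapped = int(len(unmapped))
    if sets.n_unmapped:
        logger.info("%d significant probesets had no gene mapping", sets.n_unmapped)
    mapped = sig.loc[sig.index.intersection(probe_map.index)]
    for probe, row in mapped.iterrows():
        gene = probe_map[probe]
        if row["direction"] == "down":
            sets.down.add(gene)
        elif row["direction"] == "up":
            sets.up.add(gene)
    sets.ambiguous = sets.down & sets.up
    if sets.ambiguous:
        logger.info("genes significant in both directions: %s", sorted(sets.ambiguous))
    return sets


def intersect_and_confirm(
    gene_lists: Sequence[set[str]],
    holdout: int | None = None,
) -> tuple[set[str], set[str]]:
    """Intersection of per-study gene sets, confirmed in a held-out study.

    ``holdout`` indexes the confirmation study within ``gene_lists``; the
    intersection is taken over the remaining studies and the confirmed set is
    its overlap with the holdout list.  With no holdout the confirmed set
    equals the intersection.
    """
    if holdout is not None and not 0 <= holdout < len(gene_lists):
        raise IndexError(f"holdout index {holdout} out of range")
    discovery = [s for i, s in enumerate(gene_lists) if i != holdout]
    if len(discovery) < 2:
        raise ValueError("need at least two discovery studies to intersect")
    intersection = set.intersection(*map(set, discovery))
    if holdout is None:
        return intersection, set(intersection)
    return intersection, intersection & set(gene_lists[holdout])


def gender_balance_test(counts) -> float:
    """Two-sided Fisher exact p for gender balance across disease status.

    ``counts`` is the 2x2 table of (case, control) x (male, female) sample
    counts.  A zero margin leaves independence untestable; p = 1 by
    convention.
    """
    table = np.asarray(counts, dtype=int)
    if table.shape != (2, 2) or (table < 0).any():
        raise ValueError("counts must be a non-negative 2x2 table")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        return 1.0
    return float(stats.fisher_exact(table, alternative="two-sided")[1])
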