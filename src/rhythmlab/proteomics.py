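"""Label-free differential-expression workflow for proteinGroups tables.

The pipeline mirrors the standard Perseus-style LFQ analysis:

1. drop decoy (reverse), contaminant and identified-by-site rows;
2. log2-transform the LFQ intensities;
3. keep proteins quantified in at least ``min_valid`` samples;
4. impute missing values from a downshifted normal distribution fitted per
   sample column (downshift 1.8 SD, width 0.3 SD);
5. two-sample test with a SAM-style S0 stabilization term and
   Benjamini-Hochberg FDR control;
6. one-sided Fisher's exact (hypergeometric) term enrichment of the
   significant sets against the quantified background.

The S0 statistic is d = (m2 - m1) / (s_pooled * sqrt(1/n1 + 1/n2) + S0);
S0 = 0 recovers the ordinary pooled two-sample t statistic.  p values are
taken from the t distribution with n1 + n2 - 2 degrees of freedom, which is
exact at S0 = 0 and conservative for small fold-changes at S0 > 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ProteinTable",
    "GroupDesign",
    "preprocess_protein_table",
    "impute_downshifted_normal",
    "sample_correlation_qc",
    "two_sample_s0_test",
    "bh_adjust",
    "fisher_enrichment",
]

FLAG_COLUMNS = ("only_identified_by_site", "reverse", "potential_contaminant")


@dataclass
class ProteinTable:
    """Per-protein intensities with MaxQuant-style row flags.

    ``intensities``: DataFrame (proteins x samples); NaN marks a missing
    cell.  On the raw scale all present values must be positive.
    ``flags``: boolean DataFrame with columns ``only_identified_by_site``,
    ``reverse`` and ``potential_contaminant`` (missing columns are treated
    as all-False).  ``log2_scale`` records the current intensity scale.
    """

    intensities: pd.DataFrame
    flags: pd.DataFrame | None = None
    log2_scale: bool = False

    def __post_init__(self) -> None:
        if self.intensities.shape[1] < 2:
            raise ValueError("protein table needs at least 2 sample columns")
        if self.flags is None:
            self.flags = pd.DataFrame(False, index=self.intensities.index,
                                      columns=list(FLAG_COLUMNS))
        for c in FLAG_COLUMNS:
            if c not in self.flags.columns:
                self.flags[c] = False
        self.flags = self.flags.loc[self.intensities.index, list(FLAG_COLUMNS)]
        if not self.log2_scale:
            vals = self.intensities.to_numpy(float)
            if np.nanmin(vals, initial=np.inf) <= 0:
                raise ValueError("raw-scale intensities must be positive where present")

    @property
    def samples(self) -> list[str]:
        return list(self.intensities.columns)

    @property
    def n_proteins(self) -> int:
        return len(self.intensities)

    def missing_mask(self) -> pd.DataFrame:
        return self.intensities.isna()


@dataclass
class GroupDesign:
    """Sample-to-group assignment with optional sample exclusions."""

    groups: dict[str, str]                 # sample -> group label
    excluded: list[str] = field(default_factory=list)
    group_order: tuple[str, str] | None = None

    def __post_init__(self) -> None:
        kept: dict[str, list[str]] = {}
        for s, g in self.groups.items():
            if s not in self.excluded:
                kept.setdefault(g, []).append(s)
        if len(kept) < 2 or any(len(v) < 2 for v in kept.values()):
            raise ValueError("need >= 2 groups with >= 2 samples each after exclusions")
        self._kept = kept
        if self.group_order is None:
            self.group_order = tuple(sorted(kept))[:2]

    def samples_of(self, group: str) -> list[str]:
        return list(self._kept[group])

    @property
    def retained_samples(self) -> list[str]:
        return [s for s in self.groups if s not in self.excluded]


def preprocess_protein_table(table: ProteinTable, design: GroupDesign,
                             min_valid: int = 4):
    """Flag filtering, log2 transform, and minimum-valid-values filtering.

    Returns ``(filtered_table, stage_counts)`` where ``stage_counts`` holds
    the number of protein rows after each stage (``raw``,
    ``flag_filtered``, ``min_valid_filtered``).  Excluded samples are
    dropped before counting valid values.
    """
    if table.log2_scale:
        raise ValueError("table is already log2-transformed")
    counts = {"raw": table.n_proteins}
    keep = ~table.flags.any(axis=1)
    intens = table.intensities.loc[keep, design.retained_samples]
    counts["flag_filtered"] = int(keep.sum())
    log2 = np.log2(intens)
    valid = log2.notna().sum(axis=1) >= min_valid
    log2 = log2.loc[valid]
    counts["min_valid_filtered"] = int(valid.sum())
    out = ProteinTable(log2, table.flags.loc[log2.index], log2_scale=True)
    return out, counts


def impute_downshifted_normal(table: ProteinTable, downshift: float = 1.8,
                              width: float = 0.3, per_column: bool = True,
                              seed: int = 0) -> ProteinTable:
    """Replace missing values with draws from a downshifted normal.

    For each sample column with observed mean mu and SD sigma, missing cells
    are drawn from Normal(mu - downshift * sigma, (width * sigma)^2); with
    ``per_column=False`` a single distribution is fitted to all observed
    cells.  Deterministic given ``seed``.
    """
    if not table.log2_scale:
        raise ValueError("imputation expects a log2-scale table")
    rng = np.random.default_rng(seed)
    vals = table.intensities.to_numpy(float).copy()
    if per_column:
        for j in range(vals.shape[1]):
            col = vals[:, j]
            obs = col[~np.isnan(col)]
            if obs.size < 2:
                raise ValueError(
                    f"column {table.samples[j]!r} has fewer than 2 observed values")
            mu, sigma = obs.mean(), obs.std(ddof=1)
            miss = np.isnan(col)
            col[miss] = rng.normal(mu - downshift * sigma, width * sigma,
                                   size=miss.sum())
    else:
        obs = vals[~np.isnan(vals)]
        if obs.size < 2:
            raise ValueError("fewer than 2 observed values in the table")
        mu, sigma = obs.mean(), obs.std(ddof=1)
        miss = np.isnan(vals)
        vals[miss] = rng.normal(mu - downshift * sigma, width * sigma,
                                size=int(miss.sum()))
    out = pd.DataFrame(vals, index=table.intensities.index, columns=table.samples)
    return ProteinTable(out, table.flags.copy(), log2_scale=True)


def sample_correlation_qc(table: ProteinTable, threshold: float = 0.90):
    """Pairwise Pearson correlations between samples over shared rows.

    Returns ``(corr_matrix, flagged_pairs)`` where flagged pairs have
    r <= threshold or fewer than 3 mutually observed rows (NaN entry).
    """
    if not table.log2_scale:
        raise ValueError("correlation QC expects a log2-scale table")
    corr = table.intensities.corr(method="pearson", min_periods=3)
    flagged = []
    cols = corr.columns
    for i in range(len(cols)):
        for j in range(i + 1, len(cols)):
            r = corr.iloc[i, j]
            if np.isnan(r) or r <= threshold:
                flagged.append((cols[i], cols[j], float(r)))
    return corr, flagged


def two_sample_s0_test(table: ProteinTable, design: GroupDesign,
                       s0: float = 0.1, fdr: float = 0.05,
                       welch: bool = False) -> pd.DataFrame:
    """Per-protein S0-stabilized two-sample test with BH FDR control.

    The log2 fold-change and the statistic compare ``group_order[1]`` minus
    ``group_order[0]``.  Returns a DataFrame with group means, log2 FC, the
    statistic, p and BH q values, a significance flag at ``fdr``, and the
    direction of change in group 2.
    """
    if not table.log2_scale:
        raise ValueError("test expects a log2-scale (imputed) table")
    g1, g2 = design.group_order
    x1 = table.intensities[design.samples_of(g1)].to_numpy(float)
    x2 = table.intensities[design.samples_of(g2)].to_numpy(float)
    if np.isnan(x1).any() or np.isnan(x2).any():
        raise ValueError("table contains missing values; impute first")
    n1, n2 = x1.shape[1], x2.shape[1]
    m1, m2 = x1.mean(axis=1), x2.mean(axis=1)
    v1 = x1.var(axis=1, ddof=1)
    v2 = x2.var(axis=1, ddof=1)
    if welch:
        se = np.sqrt(v1 / n1 + v2 / n2)
        dof = (v1 / n1 + v2 / n2) ** 2 / (
            (v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
    else:
        sp = np.sqrt(((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2))
        se = sp * np.sqrt(1.0 / n1 + 1.0 / n2)
        dof = np.full(m1.shape, n1 + n2 - 2)
    d = (m2 - m1) / (se + s0)
    p = 2.0 * stats.t.sf(np.abs(d), dof)
    q = bh_adjust(p)
    sig = q < fdr
    direction = np.where(~sig, "ns", np.where(m2 - m1 > 0, "up", "down"))
    return pd.DataFrame({
        f"mean_{g1}": m1, f"mean_{g2}": m2, "log2_fc": m2 - m1,
        "t_stat": d, "p_value": p, "q_value": q,
        "significant": sig, "direction": direction,
    }, index=table.intensities.index)


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p values (q values)."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise ValueError("p values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def fisher_enrichment(foreground, background, annotations: dict,
                      min_per_term: int = 3, alpha: float = 0.05) -> pd.DataFrame:
    """One-sided Fisher's exact over-representation test per annotation term.

    ``annotations`` maps term id -> set of protein ids.  For each term with
    at least ``min_per_term`` foreground members, the hypergeometric upper
    tail P(X >= k) is computed for k foreground hits out of n foreground
    proteins, K term members in the background of M proteins.  Terms are
    returned sorted by p value with an enrichment ratio
    (k/n) / (K/M) and a significance flag at ``alpha``.
    """
    fore = set(foreground)
    back = set(background)
    if not fore <= back:
        raise ValueError("foreground must be a subset of the background")
    M, n = len(back), len(fore)
    rows = []
    for term, members in annotations.items():
        in_bg = set(members) & back
        K = len(in_bg)
        k = len(in_bg & fore)
        if k < min_per_term:
            continue
        p = float(stats.hypergeom.sf(k - 1, M, K, n))
        ratio = (k / n) / (K / M) if K else np.nan
        rows.append((term, k, n, K, M, p, ratio, p < alpha))
    out = pd.DataFrame(rows, columns=["term", "k", "n", "K", "M", "p_value",
                                      "enrichment_ratio", "significant"])
    return out.sort_values("p_value", kind="mergesort").reset_index(drop=True)
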