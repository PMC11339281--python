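"""Death-state composition over time points and group comparisons.

Quantifies the fraction of NK cells in each death state per time-point group
(optionally per patient/sample), compares state fractions between groups
(Wilcoxon rank-sum / one-way ANOVA / t-test), and regresses per-patient
fractions against a clinical covariate such as lactate.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.stats

from .genesets import HEALTHY_LABEL, REPORTED_STATES


class CompositionError(ValueError):
    pass


@dataclass
class CompositionTable:
    """Counts and fractions of cells per (group[, patient]) x state."""

    counts: pd.DataFrame
    fractions: pd.DataFrame

    def to_tsv(self, path: str | Path) -> Path:
        path = Path(path)
        long = (
            self.fractions.stack()
            .rename("fraction")
            .reset_index()
            .merge(self.counts.stack().rename("count").reset_index())
        )
        long.to_csv(path, sep="\t", index=False)
        return path


def state_fractions(
    states: pd.DataFrame | np.ndarray,
    meta: pd.DataFrame | None = None,
    by: list[str] | tuple[str, ...] = ("group",),
    all_states: tuple[str, ...] | None = None,
) -> CompositionTable:
    """Exact per-group state composition.

    ``states`` is either the DeathStateTable.cells frame (barcode/state) or a
    bare state vector aligned with ``meta``.  ``by`` names the metadata
    columns to stratify on (group, or group+sample).  States absent from a
    stratum appear with count 0; fractions in every row sum to 1.
    """
    if isinstance(states, pd.DataFrame):
        df = states.set_index("barcode")[["state"]].copy()
        if meta is None:
            raise CompositionError("metadata with group labels is required")
        meta_cols = [c for c in by if c in meta.columns]
        df = df.join(meta[meta_cols], how="left")
    else:
        if meta is None or len(meta) != len(states):
            raise CompositionError("meta must align with the state vector")
        df = meta.copy()
        df["state"] = np.asarray(states)
    by = list(by)
    for col in by:
        if col not in df.columns:
            raise CompositionError(f"metadata lacks column {col!r}")
        missing = df[col].isna() | (df[col].astype(str) == "")
        if missing.any():
            raise CompositionError(
                f"cells missing {col!r}: {list(df.index[missing][:5])}"
            )
    if all_states is None:
        all_states = tuple(
            s for s in (*REPORTED_STATES, HEALTHY_LABEL) if s in set(df["state"])
        ) or tuple(sorted(set(df["state"])))
        extra = sorted(set(df["state"]) - set(all_states))
        all_states = all_states + tuple(extra)
    counts = (
        df.groupby(by)["state"]
        .value_counts()
        .unstack(fill_value=0)
        .reindex(columns=all_states, fill_value=0)
    )
    if (counts.sum(axis=1) == 0).any():
        empty = counts.index[counts.sum(axis=1) == 0].tolist()
        raise CompositionError(f"empty strata: {empty}")
    fractions = counts.div(counts.sum(axis=1), axis=0)
    return CompositionTable(counts=counts, fractions=fractions)


def compare_groups(
    values_per_group: dict[str, np.ndarray] | list[np.ndarray],
    test: str = "wilcoxon",
) -> tuple[float, float]:
    """Two-sided comparison of state fractions (or any values) across groups.

    ``wilcoxon`` (two groups; exact null enumeration when both n <= 10),
    ``t`` (two groups, Welch), or ``anova`` (>= 2 groups).  Returns
    (statistic, p).
    """
    if isinstance(values_per_group, dict):
        groups = [np.asarray(v, dtype=float) for v in values_per_group.values()]
    else:
        groups = [np.asarray(v, dtype=float) for v in values_per_group]
    if len(groups) < 2:
        raise CompositionError("need at least two groups")
    if any(len(g) < 2 for g in groups):
        raise CompositionError("each group needs at least two observations")
    if test == "wilcoxon":
        if len(groups) != 2:
            raise CompositionError("wilcoxon compares exactly two groups")
        a, b = groups
        method = "exact" if (len(a) <= 10 and len(b) <= 10) else "asymptotic"
        res = scipy.stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
        return float(res.statistic), float(res.pvalue)
    if test == "t":
        if len(groups) != 2:
            raise CompositionError("t-test compares exactly two groups")
        res = scipy.stats.ttest_ind(groups[0], groups[1], equal_var=False)
        return float(res.statistic), float(res.pvalue)
    if test == "anova":
        if all(np.var(g) == 0 for g in groups):
            raise CompositionError("degenerate variance: all groups constant")
        res = scipy.stats.f_oneway(*groups)
        return float(res.statistic), float(res.pvalue)
    raise CompositionError(f"unknown test {test!r}")


def fraction_vs_covariate(
    fractions: pd.DataFrame,
    covariate: np.ndarray | pd.Series,
) -> pd.DataFrame:
    """Ordinary least squares of each state's per-patient fraction on a
    covariate (e.g. lactate).  Returns slope, intercept, Pearson R and the
    two-sided p per state."""
    cov = np.asarray(covariate, dtype=float)
    if len(cov) != len(fractions):
        raise CompositionError("covariate length does not match fraction rows")
    if len(cov) < 3:
        raise CompositionError("need at least 3 paired observations")
    if np.ptp(cov) == 0:
        raise CompositionError("constant covariate")
    rows = []
    for state in fractions.columns:
        y = fractions[state].to_numpy(dtype=float)
        res = scipy.stats.linregress(cov, y)
        rows.append(
            {
                "state": state,
                "slope": res.slope,
                "intercept": res.intercept,
                "r": res.rvalue,
                "p": res.pvalue,
            }
        )
    return pd.DataFrame(rows).set_index("state")
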