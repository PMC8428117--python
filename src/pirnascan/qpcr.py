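"""Relative copy-number / expression estimation by the Livak 2^-ddCt method.

Per replicate, dCt = Ct(target) - Ct(reference); ddCt is the difference of
group-mean dCt between test and control, and the relative quantity is
2^-ddCt (assuming perfect doubling per cycle, as the method does). Group
comparison uses an unpaired t-test on the per-replicate dCt values —
Welch's unequal-variance form by default, Student's by flag.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

REQUIRED_COLUMNS = ["sample_group", "replicate_id", "gene_role", "ct"]


class CtTableError(ValueError):
    pass


@dataclass(frozen=True)
class CopyNumberResult:
    delta_ct_test: float
    delta_ct_control: float
    delta_delta_ct: float
    fold_change: float
    fold_reduction: float
    se: float | None
    t_stat: float | None
    df: float | None
    p_value: float | None
    n_test: int
    n_control: int

    def summary(self) -> str:
        lines = [
            "Livak relative quantification (2^-ddCt)",
            f"  mean dCt test     {self.delta_ct_test: .4f}  (n={self.n_test})",
            f"  mean dCt control  {self.delta_ct_control: .4f}  (n={self.n_control})",
            f"  ddCt              {self.delta_delta_ct: .4f}",
            f"  fold change       {self.fold_change: .4f}",
            f"  fold reduction    {self.fold_reduction: .4f}",
        ]
        if self.p_value is not None:
            lines.append(
                f"  unpaired t-test   t={self.t_stat:.4f}, df={self.df:.2f}, "
                f"p={self.p_value:.4g} (se of ddCt {self.se:.4f})"
            )
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "delta_ct_test": self.delta_ct_test,
            "delta_ct_control": self.delta_ct_control,
            "delta_delta_ct": self.delta_delta_ct,
            "fold_change": self.fold_change,
            "fold_reduction": self.fold_reduction,
            "se": self.se,
            "t": self.t_stat,
            "df": self.df,
            "p_value": self.p_value,
            "n_test": self.n_test,
            "n_control": self.n_control,
        }


def load_ct_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#")
    return validate_ct_table(df)


def validate_ct_table(df: pd.DataFrame) -> pd.DataFrame:
    missing = set(REQUIRED_COLUMNS) - set(df.columns)
    if missing:
        raise CtTableError(f"Ct table lacks columns {sorted(missing)}")
    if not set(df["sample_group"]) == {"test", "control"}:
        raise CtTableError("sample_group must contain exactly {test, control}")
    if not set(df["gene_role"]) <= {"target", "reference"}:
        raise CtTableError("gene_role must be target or reference")
    if (df["ct"] <= 0).any():
        raise CtTableError("Ct values must be positive")
    return df


def ttest_unpaired(x, y, welch: bool = True) -> tuple[float, float, float]:
    """Unpaired two-sample t-test: (t, df, two-sided p).

    Welch's unequal-variance form by default (Welch-Satterthwaite df).
    Zero variance in both groups with equal means returns p = 1 by
    convention (no evidence of a difference, not an error).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("need >= 2 observations per group")
    if np.var(x, ddof=1) == 0 and np.var(y, ddof=1) == 0:
        if np.mean(x) == np.mean(y):
            df = len(x) + len(y) - 2
            return 0.0, float(df), 1.0
        return math.inf, float(len(x) + len(y) - 2), 0.0
    res = stats.ttest_ind(x, y, equal_var=not welch)
    df = float(res.df)
    return float(res.statistic), df, float(res.pvalue)


def _delta_cts(df: pd.DataFrame, group: str) -> np.ndarray:
    sub = df[df["sample_group"] == group]
    piv = sub.pivot_table(
        index="replicate_id", columns="gene_role", values="ct", aggfunc="mean"
    )
    if "target" not in piv.columns or "reference" not in piv.columns:
        raise CtTableError(f"group {group!r}: a replicate lacks target or reference")
    if piv[["target", "reference"]].isna().any().any():
        raise CtTableError(f"group {group!r}: a replicate lacks target or reference")
    return (piv["target"] - piv["reference"]).to_numpy(dtype=float)


def livak(df: pd.DataFrame, welch: bool = True) -> CopyNumberResult:
    """Livak 2^-ddCt quantification of test vs control from a Ct table.

    dCt is computed within replicate (replicate ids pair target and
    reference wells); statistics come from an unpaired t-test on the
    per-replicate dCt values and are suppressed (with a warning) when a
    group has fewer than two replicates.
    """
    df = validate_ct_table(df)
    d_test = _delta_cts(df, "test")
    d_control = _delta_cts(df, "control")
    ddct = float(np.mean(d_test) - np.mean(d_control))
    fold = float(2.0 ** (-ddct))
    se = t = dof = p = None
    if len(d_test) >= 2 and len(d_control) >= 2:
        t, dof, p = ttest_unpaired(d_test, d_control, welch=welch)
        se = float(
            math.sqrt(
                np.var(d_test, ddof=1) / len(d_test)
                + np.var(d_control, ddof=1) / len(d_control)
            )
        )
    else:
        warnings.warn("fewer than 2 replicates in a group: statistics suppressed")
    return CopyNumberResult(
        delta_ct_test=float(np.mean(d_test)),
        delta_ct_control=float(np.mean(d_control)),
        delta_delta_ct=ddct,
        fold_change=fold,
        fold_reduction=1.0 / fold,
        se=se,
        t_stat=t,
        df=dof,
        p_value=p,
        n_test=len(d_test),
        n_control=len(d_control),
    )
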