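"""Bench-side quantification procedures.

Covers relative qPCR quantification by 2^-ddCt, two-channel reporter
knockdown normalization (readout MFI over transfection-control MFI,
per well, then averaged, then scaled to the empty-vector average),
within-host chimera MFI normalization against a congenic reference
population, and the normality-gated two-sample test dispatch
(Shapiro-Wilk on each group; Welch t when both pass, Mann-Whitney U
otherwise).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class RelExpr:
    """2^-ddCt output for one target gene."""

    gene: str
    delta_ct_control: float
    delta_ct_treated: float
    delta_delta_ct: float
    fold_change: float


@dataclass
class StatReport:
    """Which two-sample route fired and its result."""

    test: str  # welch_t | mann_whitney
    statistic: float
    p_value: float
    shapiro_p_a: float
    shapiro_p_b: float
    note: str = ""


def _validate_ct(ct: pd.DataFrame) -> pd.DataFrame:
    required = {"sample", "condition", "role", "gene", "ct"}
    missing = required - set(ct.columns)
    if missing:
        raise ValueError(f"Ct table missing columns: {sorted(missing)}")
    if not np.isfinite(ct["ct"].to_numpy(dtype=float)).all():
        raise ValueError("non-finite Ct value in table")
    bad = set(ct["condition"]) - {"treated", "control"}
    if bad:
        raise ValueError(f"unknown condition labels {sorted(bad)}")
    return ct


def ddct_relative_expression(ct: pd.DataFrame) -> list[RelExpr]:
    """Relative expression by the 2^-ddCt method.

    Replicate Ct values are averaged per (condition, gene) first;
    dCt = Ct_target - Ct_reference within each condition;
    ddCt = dCt_treated - dCt_control; fold = 2^-ddCt.
    """
    ct = _validate_ct(pd.DataFrame(ct))
    out = []
    for cond in ("treated", "control"):
        if not ((ct["condition"] == cond) & (ct["role"] == "reference")).any():
            raise ValueError(f"missing reference gene for condition {cond!r}")
    ref_ct = {
        cond: ct[(ct["condition"] == cond) & (ct["role"] == "reference")]["ct"].mean()
        for cond in ("treated", "control")
    }
    targets = ct[ct["role"] == "target"]
    for gene, sub in targets.groupby("gene", sort=False):
        d = {}
        for cond in ("treated", "control"):
            cond_ct = sub[sub["condition"] == cond]["ct"]
            if cond_ct.empty:
                raise ValueError(
                    f"gene {gene!r}: no target Ct for condition {cond!r}")
            d[cond] = cond_ct.mean() - ref_ct[cond]
        ddct = d["treated"] - d["control"]
        out.append(RelExpr(gene=gene,
                           delta_ct_control=float(d["control"]),
                           delta_ct_treated=float(d["treated"]),
                           delta_delta_ct=float(ddct),
                           fold_change=float(2.0 ** (-ddct))))
    return out


def reporter_knockdown(mfi: pd.DataFrame,
                       readout_marker: str = "NGFR",
                       control_marker: str = "Thy1.1",
                       test_vector: str = "mir",
                       reference_vector: str = "empty") -> float:
    """Normalized reporter value of a miRNA expression vector.

    Per well, the readout-channel MFI is divided by the transfection-
    control MFI; replicate well ratios are averaged per vector; the
    test-vector average is divided by the reference-vector average
    (which is thereby set to 1).  Values below 1 indicate knockdown
    of the reporter by the miRNA.
    """
    df = pd.DataFrame(mfi)
    required = {"well", "vector", "marker", "mfi"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"MFI table missing columns: {sorted(missing)}")
    if (df["mfi"] <= 0).any():
        bad = df.loc[df["mfi"] <= 0].iloc[0]
        raise ValueError(
            f"non-positive MFI in well {bad['well']!r}, marker {bad['marker']!r}")
    wide = df.pivot_table(index=["vector", "well"], columns="marker",
                          values="mfi", aggfunc="mean")
    for mk in (readout_marker, control_marker):
        if mk not in wide.columns:
            raise ValueError(f"marker {mk!r} absent from MFI table")
    if wide[[readout_marker, control_marker]].isna().any().any():
        raise ValueError("a well lacks one of the two marker channels")
    ratios = wide[readout_marker] / wide[control_marker]
    means = ratios.groupby(level="vector").mean()
    for v in (test_vector, reference_vector):
        if v not in means.index:
            raise ValueError(f"vector {v!r} absent from MFI table")
    return float(means[test_vector] / means[reference_vector])


def chimera_normalize(records: pd.DataFrame,
                      test_population: str = "CD45.2",
                      reference_population: str = "CD45.1") -> pd.DataFrame:
    """Within-host normalization of marker MFIs on a test population
    against a congenic reference population.

    Returns a host x marker frame of MFI_test / MFI_reference ratios.
    Hosts missing the reference (or test) population for a marker are
    skipped with a warning.
    """
    df = pd.DataFrame(records)
    required = {"host", "population", "marker", "mfi"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"MFI table missing columns: {sorted(missing)}")
    if (df["mfi"] <= 0).any():
        raise ValueError("non-positive MFI value")
    rows = []
    for (host, marker), sub in df.groupby(["host", "marker"], sort=False):
        test = sub[sub["population"] == test_population]["mfi"]
        ref = sub[sub["population"] == reference_population]["mfi"]
        if test.empty or ref.empty:
            warnings.warn(
                f"host {host!r}, marker {marker!r}: missing "
                f"{'reference' if ref.empty else 'test'} population; skipped",
                stacklevel=2)
            continue
        rows.append({"host": host, "marker": marker,
                     "ratio": float(test.mean() / ref.mean())})
    return (pd.DataFrame(rows)
            .pivot(index="host", columns="marker", values="ratio"))


def stat_dispatch(group_a, group_b, alpha_normality: float = 0.05) -> StatReport:
    """Normality-gated two-sample comparison.

    Shapiro-Wilk is run on each group; if both p-values are at or
    above ``alpha_normality`` the groups are compared with a
    two-tailed Welch t test, otherwise with a two-sided Mann-Whitney
    U.  Zero variance in both groups (Welch undefined) forces the
    Mann-Whitney route.  The exact U distribution is used for small
    tie-free samples (both n <= 8), the tie-corrected normal
    approximation otherwise.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 3 or len(b) < 3:
        raise ValueError("each group needs at least 3 observations")
    note = ""
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        sw_a = sw_b = np.nan
        route = "mann_whitney"
        note = "zero variance in both groups; Welch t undefined"
    else:
        # Shapiro-Wilk is undefined for a constant group; treat it as
        # a normality failure
        sw_a = stats.shapiro(a).pvalue if np.ptp(a) > 0 else 0.0
        sw_b = stats.shapiro(b).pvalue if np.ptp(b) > 0 else 0.0
        route = ("welch_t"
                 if sw_a >= alpha_normality and sw_b >= alpha_normality
                 else "mann_whitney")
    if route == "welch_t":
        res = stats.ttest_ind(a, b, equal_var=False)
        return StatReport(test="welch_t", statistic=float(res.statistic),
                          p_value=float(res.pvalue),
                          shapiro_p_a=float(sw_a), shapiro_p_b=float(sw_b))
    ties = len(np.unique(np.concatenate([a, b]))) < len(a) + len(b)
    method = "exact" if (max(len(a), len(b)) <= 8 and not ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return StatReport(test="mann_whitney", statistic=float(res.statistic),
                      p_value=float(res.pvalue),
                      shapiro_p_a=float(sw_a), shapiro_p_b=float(sw_b),
                      note=note)
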