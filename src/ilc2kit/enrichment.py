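"""Gene-set overrepresentation and enrichment on DE output.

Two complementary tests: an upper-tail hypergeometric test of a
discrete DE gene list against each set (overrepresentation), and a
score-based enrichment test comparing the per-gene statistics (e.g.
posterior-mean average effects) of set members against non-members
with a Welch two-sample t (a simplified, score-level variant of the
generally-applicable gene-set enrichment idea).  Benjamini-Hochberg
adjustment is applied across sets within each method.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


@dataclass
class GeneSet:
    set_id: str
    name: str
    members: frozenset

    def __post_init__(self):
        self.members = frozenset(self.members)
        if not self.members:
            raise ValueError(f"gene set {self.set_id!r} is empty")


def read_gmt(path) -> list[GeneSet]:
    """Read a GMT file: tab-separated set id, description, members."""
    sets = []
    for line_no, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"{path}:{line_no}: GMT line has <3 fields")
        sets.append(GeneSet(set_id=parts[0], name=parts[1],
                            members=frozenset(p for p in parts[2:] if p)))
    return sets


def write_gmt(sets: list[GeneSet], path) -> None:
    lines = [
        "\t".join([s.set_id, s.name, *sorted(s.members)]) for s in sets
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def hypergeom_overrep(de_genes, universe, sets: list[GeneSet]) -> pd.DataFrame:
    """Upper-tail hypergeometric overrepresentation test per set.

    With universe size N, set size m (after intersecting with the
    universe), DE-list size n and overlap k, reports
    P(X >= k), X ~ Hypergeom(N, m, n), plus BH-adjusted q across sets.
    """
    de = set(de_genes)
    uni = set(universe)
    if not uni:
        raise ValueError("empty universe")
    if not de:
        raise ValueError("empty DE list")
    if not de <= uni:
        raise ValueError("de_genes must be a subset of the universe")
    N, n = len(uni), len(de)
    rows = []
    for gs in sets:
        members = gs.members & uni
        m = len(members)
        k = len(members & de)
        # sf(k-1) = P(X >= k)
        p = float(stats.hypergeom.sf(k - 1, N, m, n))
        rows.append({"set_id": gs.set_id, "name": gs.name, "k": k, "m": m,
                     "n": n, "N": N, "p": min(p, 1.0)})
    out = pd.DataFrame(rows)
    if len(out):
        out["q"] = multipletests(out["p"], method="fdr_bh")[1]
    return out


def gage_enrichment(per_gene_stats: pd.Series, sets: list[GeneSet],
                    direction: str = "two_sided") -> pd.DataFrame:
    """Score-level gene-set enrichment: Welch t of member vs
    non-member per-gene scores.

    ``direction='up'`` tests for member scores above background,
    ``'down'`` below, ``'two_sided'`` either.  Sets with fewer than 2
    scored members (or fewer than 2 non-members) are skipped with a
    warning.  Reports the t statistic, Welch-Satterthwaite df, p and
    BH-adjusted q.
    """
    if direction not in ("two_sided", "up", "down"):
        raise ValueError(f"unknown direction {direction!r}")
    scores = pd.Series(per_gene_stats).astype(float)
    if not np.isfinite(scores).all():
        raise ValueError("per-gene scores must be finite")
    rows = []
    for gs in sets:
        members = [g for g in scores.index if g in gs.members]
        others = [g for g in scores.index if g not in gs.members]
        if len(members) < 2 or len(others) < 2:
            warnings.warn(
                f"set {gs.set_id!r}: fewer than 2 scored members or "
                "non-members; skipped", stacklevel=2)
            continue
        x, yv = scores[members].to_numpy(), scores[others].to_numpy()
        t, df = welch_t(x, yv)
        if direction == "two_sided":
            p = 2 * stats.t.sf(abs(t), df)
        elif direction == "up":
            p = stats.t.sf(t, df)
        else:
            p = stats.t.cdf(t, df)
        rows.append({"set_id": gs.set_id, "name": gs.name,
                     "n_members": len(members), "t": t, "df": df,
                     "p": float(p)})
    out = pd.DataFrame(rows)
    if len(out):
        out["q"] = multipletests(out["p"], method="fdr_bh")[1]
    return out


def welch_t(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Unequal-variance two-sample t statistic and its
    Welch-Satterthwaite degrees of freedom."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    nx, ny = len(x), len(y)
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    se2 = vx / nx + vy / ny
    if se2 == 0:
        raise ZeroDivisionError("both groups have zero variance")
    t = (x.mean() - y.mean()) / np.sqrt(se2)
    df = se2**2 / ((vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1))
    return float(t), float(df)
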