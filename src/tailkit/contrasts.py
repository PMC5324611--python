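"""Phylogenetically independent contrasts (Felsenstein 1985).

Under Brownian-motion trait evolution on a known tree, differences between
the (weighted-average) trait values of the two daughters of each internal
node are independent, and dividing each difference by the square root of the
sum of the daughters' (adjusted) branch lengths gives contrasts that are
i.i.d. normal with the Brownian rate as variance.  Regressing the contrasts
of one trait on those of another *through the origin* is the standard test
of correlated evolution and is algebraically identical to phylogenetic GLS
with the tree covariance.

The pruning recursion: at an internal node with daughters carrying values
(x1, x2) on branches (v1, v2),

    contrast  = (x1 - x2) / sqrt(v1 + v2)
    node value = (x1/v1 + x2/v2) / (1/v1 + 1/v2)
    parent branch adjustment: v' = v + v1*v2/(v1 + v2).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .trees import PhyloTree

_MIN_BRANCH = 1e-12


@dataclass
class ContrastSet:
    node_ids: list
    x: np.ndarray          # standardized contrasts, trait X
    y: np.ndarray          # standardized contrasts, trait Y
    variance: np.ndarray   # contrast variances (sum of adjusted branches)

    def __len__(self) -> int:
        return len(self.x)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"node": self.node_ids, "contrast_x": self.x,
                             "contrast_y": self.y, "variance": self.variance})


def _prune(node, traits, out, counter):
    """Post-order pruning; returns (values array, adjusted branch length)."""
    if node.is_tip():
        return np.asarray(traits[node.name], float), max(node.length or 0.0, _MIN_BRANCH)
    children = node.children
    vals, lens = zip(*(_prune(c, traits, out, counter) for c in children))
    if len(children) == 1:  # unary pass-through (can arise from rooting)
        return vals[0], (node.length or 0.0) + lens[0]
    # bifurcating by construction (zero-length resolution upstream)
    (x1, v1), (x2, v2) = (vals[0], lens[0]), (vals[1], lens[1])
    v1 = max(v1, _MIN_BRANCH)
    v2 = max(v2, _MIN_BRANCH)
    vsum = v1 + v2
    out.append(((x1 - x2) / np.sqrt(vsum), vsum, counter[0]))
    counter[0] += 1
    value = (x1 / v1 + x2 / v2) / (1.0 / v1 + 1.0 / v2)
    branch = (node.length or 0.0) + v1 * v2 / vsum
    return value, branch


def pic_contrasts(tree: PhyloTree, x: dict, y: dict) -> ContrastSet:
    """Standardized independent contrasts for two traits defined at the tips.

    The tree is midpoint-rooted and polytomies are resolved with zero-length
    edges before pruning; traits are dicts keyed by tip name.  Returns
    tips - 1 contrasts.
    """
    tips = tree.tips
    for name, trait in (("x", x), ("y", y)):
        miss = [t for t in tips if t not in trait]
        if miss:
            raise ValueError(f"trait {name} missing for tips {miss}")
    traits = {t: np.array([float(x[t]), float(y[t])]) for t in tips}
    if len(tips) == 2:  # single contrast; no rooting needed
        a, b = (t for t in tree.root.tips())
        vsum = max(a.length or 0.0, _MIN_BRANCH) + max(b.length or 0.0,
                                                       _MIN_BRANCH)
        contrast = (traits[a.name] - traits[b.name]) / np.sqrt(vsum)
        return ContrastSet(node_ids=["node0"], x=np.array([contrast[0]]),
                           y=np.array([contrast[1]]),
                           variance=np.array([vsum]))
    rooted = tree.rooted_bifurcating()
    out: list = []
    _prune(rooted.root, traits, out, [0])
    contrasts = np.array([c for c, _, _ in out])
    variances = np.array([v for _, v, _ in out])
    ids = [f"node{n}" for _, _, n in out]
    return ContrastSet(node_ids=ids, x=contrasts[:, 0], y=contrasts[:, 1],
                       variance=variances)


@dataclass
class ContrastRegression:
    slope: float
    se: float
    r2_adjusted: float
    p_value: float
    n_contrasts: int


def contrast_regression(c: ContrastSet) -> ContrastRegression:
    """Least squares of Y-contrasts on X-contrasts through the origin.

    The intercept is omitted because contrasts have arbitrary sign.  Returns
    the slope with its two-sided p-value and the (uncentred) adjusted R^2.
    """
    if len(c) < 3:
        raise ValueError("at least three contrasts required")
    if not np.any(np.abs(c.x) > 0):
        raise ValueError("all X-contrasts are zero; slope undefined")
    fit = sm.OLS(c.y, c.x[:, None]).fit()
    return ContrastRegression(slope=float(fit.params[0]),
                              se=float(fit.bse[0]),
                              r2_adjusted=float(fit.rsquared_adj),
                              p_value=float(fit.pvalues[0]),
                              n_contrasts=len(c))
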