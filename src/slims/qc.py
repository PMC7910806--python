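"""Locus-recovery QC and its two statistical analyses.

A targeted locus counts as recovered when it assembles to at least 6x
reference coverage and 350 bp; high-copy loci (organellar/rDNA-like
targets that recover trivially) are excluded from both numerator and
denominator. A sample fails sequencing when under 5% (strict) of its
scored loci are recovered. Recovery structure is then examined two ways:
a one-way fixed-effects ANOVA of per-sample recovery grouped by family
with an eta-squared effect size, and an ordinary least-squares regression
of recovery on the patristic distance to the nearest bait-design taxon.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd
from scipy import stats

from .config import ProjectConfig
from .taxonomy import normalize_name


def classify_locus(coverage: float, length_bp: int, high_copy: bool = False,
                   config: ProjectConfig | None = None) -> bool | None:
    """True = recovered, False = not recovered, None = not scored
    (high-copy locus)."""
    config = config or ProjectConfig()
    if high_copy:
        return None
    return coverage >= config.coverage_min and length_bp >= config.length_min_bp


@dataclass(frozen=True)
class QCSummary:
    sample_uuid: str
    n_loci_scored: int
    n_success: int
    failed: bool

    @property
    def fraction(self) -> float:
        return self.n_success / self.n_loci_scored


class UnscorableSampleError(ValueError):
    """Every locus of the sample is high-copy; no recovery fraction exists."""


def summarize_sample(sample_uuid: str,
                     records: list[tuple[float, int, bool]],
                     config: ProjectConfig | None = None) -> QCSummary:
    """Per-sample QC from (coverage, length_bp, high_copy) locus records.

    The failure flag uses a strict inequality: exactly 5% of loci recovered
    is not a failure.
    """
    config = config or ProjectConfig()
    n_scored = 0
    n_success = 0
    for cov, length, high_copy in records:
        outcome = classify_locus(cov, length, high_copy, config)
        if outcome is None:
            continue
        n_scored += 1
        n_success += outcome
    if n_scored == 0:
        raise UnscorableSampleError(
            f"sample {sample_uuid}: all loci are high-copy")
    fraction = n_success / n_scored
    return QCSummary(sample_uuid, n_scored, n_success,
                     failed=fraction < config.failure_fraction)


def summarize_all(db, config: ProjectConfig | None = None) -> pd.DataFrame:
    """QC summaries for every sample with locus data; persists qc_summary."""
    config = config or db.config
    df = db.table_frame("locus_recovery")
    out = []
    for uuid, grp in df.groupby("sample_uuid", sort=True):
        recs = list(zip(grp["reference_coverage"], grp["assembled_length"],
                        grp["high_copy"].astype(bool)))
        try:
            s = summarize_sample(uuid, recs, config)
        except UnscorableSampleError:
            continue
        out.append({"sample_uuid": s.sample_uuid,
                    "n_loci_scored": s.n_loci_scored,
                    "n_success": s.n_success, "fraction": s.fraction,
                    "failed": s.failed})
    res = pd.DataFrame(
        out, columns=["sample_uuid", "n_loci_scored", "n_success",
                      "fraction", "failed"])
    db.conn.execute("DELETE FROM qc_summary")
    for r in out:
        db.conn.execute(
            "INSERT INTO qc_summary (sample_uuid, n_loci_scored, n_success,"
            " fraction, failed) VALUES (?,?,?,?,?)",
            (r["sample_uuid"], r["n_loci_scored"], r["n_success"],
             r["fraction"], int(r["failed"])))
    db.conn.commit()
    return res


@dataclass(frozen=True)
class AnovaResult:
    F: float
    p: float
    eta_squared: float
    ss_between: float
    ss_within: float
    group_sizes: dict[str, int]


def anova_by_family(values: pd.Series | np.ndarray,
                    families: pd.Series | np.ndarray,
                    min_n: int = 50) -> tuple[AnovaResult, pd.DataFrame]:
    """One-way fixed-effects ANOVA of per-sample recovery grouped by family.

    eta^2 = SS_between / SS_total. The ANOVA uses every sample; the
    companion five-number-summary table is restricted to families with at
    least `min_n` samples (the reporting cutoff).
    """
    y = np.asarray(values, dtype=float)
    g = np.asarray(families, dtype=object)
    if y.size != g.size:
        raise ValueError("values and families differ in length")
    labels = pd.unique(g)
    if len(labels) < 2:
        raise ValueError("ANOVA needs at least 2 families")
    grand = y.mean()
    ss_total = float(((y - grand) ** 2).sum())
    ss_between = 0.0
    ss_within = 0.0
    sizes: dict[str, int] = {}
    summaries = []
    for lab in sorted(labels):
        yi = y[g == lab]
        sizes[str(lab)] = yi.size
        mi = yi.mean()
        ss_between += yi.size * (mi - grand) ** 2
        ss_within += float(((yi - mi) ** 2).sum())
        if yi.size >= min_n:
            q0, q1, q2, q3, q4 = np.percentile(yi, [0, 25, 50, 75, 100])
            summaries.append({"family": str(lab), "n": int(yi.size),
                              "min": q0, "q1": q1, "median": q2, "q3": q3,
                              "max": q4, "mean": mi})
    k = len(labels)
    n = y.size
    if ss_total == 0:
        f_stat, p, eta2 = 0.0, 1.0, 0.0
    elif ss_within == 0:
        f_stat, p, eta2 = math.inf, 0.0, 1.0
    else:
        f_stat = (ss_between / (k - 1)) / (ss_within / (n - k))
        p = float(stats.f.sf(f_stat, k - 1, n - k))
        eta2 = ss_between / ss_total
    table = pd.DataFrame(
        summaries, columns=["family", "n", "min", "q1", "median", "q3",
                            "max", "mean"])
    return AnovaResult(f_stat, p, eta2, ss_between, ss_within, sizes), table


class BaitDistanceCalculator:
    """Patristic distance from any tree tip to its nearest bait-design
    taxon: the minimum over baits of the branch-length sum along the
    tip-to-bait path.

    Tip labels are matched through the same binomial normalisation used by
    the taxonomy module. Tips absent from the tree are reported as
    unmapped, never imputed.
    """

    def __init__(self, tree: dendropy.Tree | str, bait_taxa: list[str]):
        if not isinstance(tree, dendropy.Tree):
            tree = dendropy.Tree.get(data=str(tree), schema="newick")
        self.tree = tree
        # Undirected weighted graph over the tree's nodes.
        adj: dict[int, list[tuple[int, float]]] = {}
        self._leaf_nodes: dict[str, int] = {}
        for edge in tree.preorder_edge_iter():
            if edge.tail_node is None:
                continue
            a, b = id(edge.tail_node), id(edge.head_node)
            w = float(edge.length or 0.0)
            adj.setdefault(a, []).append((b, w))
            adj.setdefault(b, []).append((a, w))
        for leaf in tree.leaf_node_iter():
            key = self._norm(leaf.taxon.label)
            if key is not None:
                self._leaf_nodes[key] = id(leaf)
        bait_nodes = []
        for bait in bait_taxa:
            key = self._norm(bait)
            if key in self._leaf_nodes:
                bait_nodes.append(self._leaf_nodes[key])
        if not bait_nodes:
            raise ValueError("no bait taxon is present in the tree")
        # One Dijkstra-style relaxation per bait; tree paths are unique so
        # a simple stack traversal suffices.
        self._dist_to_nearest_bait: dict[int, float] = {}
        for start in bait_nodes:
            dist = {start: 0.0}
            stack = [start]
            while stack:
                node = stack.pop()
                for nbr, w in adj.get(node, ()):
                    if nbr not in dist:
                        dist[nbr] = dist[node] + w
                        stack.append(nbr)
            for node, d in dist.items():
                cur = self._dist_to_nearest_bait.get(node)
                if cur is None or d < cur:
                    self._dist_to_nearest_bait[node] = d

    @staticmethod
    def _norm(label: str) -> str | None:
        return normalize_name(label.replace("_", " "))

    def distance(self, tip_name: str) -> float | None:
        """Nearest-bait patristic distance, or None when the tip is not in
        the tree (unmapped)."""
        key = self._norm(tip_name)
        if key is None or key not in self._leaf_nodes:
            return None
        return self._dist_to_nearest_bait[self._leaf_nodes[key]]

    def distances(self, tip_names: list[str]) -> tuple[dict[str, float], int]:
        """(mapped tip -> distance, number unmapped)."""
        out: dict[str, float] = {}
        unmapped = 0
        for name in tip_names:
            d = self.distance(name)
            if d is None:
                unmapped += 1
            else:
                out[name] = d
        return out, unmapped


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    p: float
    r_squared: float
    adjusted_r_squared: float
    n: int


class DegenerateRegressionError(ValueError):
    pass


def distance_regression(distances: np.ndarray,
                        loci_counts: np.ndarray) -> RegressionResult:
    """OLS of recovered-locus count on nearest-bait patristic distance.

    Reports the slope, its two-sided p-value, and adjusted R^2 =
    1 - (1 - R^2)(n - 1)/(n - 2).
    """
    x = np.asarray(distances, dtype=float)
    y = np.asarray(loci_counts, dtype=float)
    n = x.size
    if n < 3:
        raise ValueError("regression needs at least 3 mapped samples")
    sxx = float(((x - x.mean()) ** 2).sum())
    if sxx == 0:
        raise DegenerateRegressionError("distances have zero variance")
    sxy = float(((x - x.mean()) * (y - y.mean())).sum())
    slope = sxy / sxx
    intercept = float(y.mean() - slope * x.mean())
    resid = y - (intercept + slope * x)
    ss_res = float((resid ** 2).sum())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    adj = 1.0 - (1.0 - r2) * (n - 1) / (n - 2)
    if ss_res == 0:
        p = 0.0
    else:
        se = math.sqrt(ss_res / (n - 2) / sxx)
        p = float(2 * stats.t.sf(abs(slope) / se, n - 2))
    return RegressionResult(slope, intercept, p, r2, adj, n)
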