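"""Node-dated cospeciation dataset and uncertainty-propagating resampling.

The evidence for a time-dependent rate analysis on a virus-host
cospeciation system is, per internal node of the fixed viral phylogeny:

* a posterior sample of node-to-tip substitutions per site ``s`` (the
  node's height on the substitution-unit tree, strict clock, aligned tips);
* for host-dated nodes, a calibration timescale ``t`` in Myr summarised as
  a median and a 95 % interval, treated as normal with sd derived from the
  wider half-interval.

Uncertainty in s, t and rbar = s/t is propagated by resampling: normal t
draws constrained so every child node is younger than its parent, randomly
paired with posterior s samples, giving many ``RateSampleSet`` replicates
on which the decay models are fitted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import dendropy
import numpy as np

from .models import YEARS_PER_MYR

__all__ = [
    "CalibrationPrior",
    "NodeRecord",
    "CospeciationDataset",
    "RateSampleSet",
    "sigma_from_interval",
    "node_heights",
    "simulate_calibration_times",
    "assemble_rate_sets",
]

#: draws are truncated below at this age (Myr): no non-positive times
MIN_TIME_MYR = 1e-6

#: per-node, per-row cap on truncated-normal rejection attempts
MAX_ATTEMPTS = 1000


def sigma_from_interval(median: float, lower95: float, upper95: float) -> float:
    """Normal sd implied by a median and 95 % interval: the wider half-width / 1.96."""
    if not lower95 <= median <= upper95:
        raise ValueError(
            f"interval ordering violated: lower {lower95} <= median {median} "
            f"<= upper {upper95} required"
        )
    return max((median - lower95) / 1.96, (upper95 - median) / 1.96)


@dataclass(frozen=True)
class CalibrationPrior:
    """Host-derived node age: median and 95 % bounds in Myr, normal sd derived."""

    median: float
    lower95: float
    upper95: float
    sd: float = field(init=False)

    def __post_init__(self):
        if self.median <= 0:
            raise ValueError(f"calibration median must be > 0 Myr, got {self.median}")
        object.__setattr__(
            self, "sd", sigma_from_interval(self.median, self.lower95, self.upper95)
        )


@dataclass
class NodeRecord:
    """One internal node: its s posterior sample and optional calibration."""

    node_id: str
    parent_id: Optional[str]
    s_samples: np.ndarray
    calibration: Optional[CalibrationPrior] = None
    s_reconstructed: bool = False  # draws rebuilt from a summary, not true posterior

    def __post_init__(self):
        self.s_samples = np.asarray(self.s_samples, dtype=float)
        if self.s_samples.size == 0:
            raise ValueError(f"node {self.node_id}: s_samples must be nonempty")
        if np.any(self.s_samples <= 0):
            raise ValueError(f"node {self.node_id}: all s samples must be > 0")

    @property
    def is_dated(self) -> bool:
        return self.calibration is not None

    @property
    def s_median(self) -> float:
        return float(np.median(self.s_samples))


def reconstruct_s_samples(
    median: float,
    lower95: float,
    upper95: float,
    n_draws: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Log-normal draws matching a (median, 95 % interval) s summary.

    Used when only a summary of the s posterior is available; posterior
    branch-length distributions are positive and right-skewed, which the
    log-normal matches.  Records built this way are flagged reconstructed.
    """
    if not 0 < lower95 <= median <= upper95:
        raise ValueError("require 0 < lower95 <= median <= upper95")
    sigma = max(
        (math.log(median) - math.log(lower95)) / 1.96,
        (math.log(upper95) - math.log(median)) / 1.96,
    )
    return median * np.exp(sigma * rng.standard_normal(n_draws))


class CospeciationDataset:
    """Rooted ultrametric tree plus per-node s samples and calibration priors.

    Validates on construction: unique root, child calibration medians below
    their nearest dated ancestor's, s medians non-decreasing child-to-parent,
    and (if a tree is attached) ultrametricity of its substitution-unit
    branch lengths.
    """

    def __init__(
        self,
        nodes: Sequence[NodeRecord],
        tree: Optional[dendropy.Tree] = None,
    ):
        self.nodes: Dict[str, NodeRecord] = {}
        for rec in nodes:
            if rec.node_id in self.nodes:
                raise ValueError(f"duplicate node_id {rec.node_id!r}")
            self.nodes[rec.node_id] = rec
        self.tree = tree
        self._validate()

    def _validate(self) -> None:
        roots = [r for r in self.nodes.values() if r.parent_id is None]
        if len(roots) != 1:
            raise ValueError(f"expected exactly one root node, found {len(roots)}")
        for rec in self.nodes.values():
            if rec.parent_id is not None and rec.parent_id not in self.nodes:
                raise ValueError(
                    f"node {rec.node_id}: unknown parent {rec.parent_id!r}"
                )
        for rec in self.nodes.values():
            anc = self._nearest_dated_ancestor(rec)
            if rec.is_dated and anc is not None:
                if not rec.calibration.median < anc.calibration.median:
                    raise ValueError(
                        f"node {rec.node_id}: calibration median "
                        f"{rec.calibration.median} not below dated ancestor "
                        f"{anc.node_id}'s {anc.calibration.median}"
                    )
            if rec.parent_id is not None:
                parent = self.nodes[rec.parent_id]
                # small relative slack: medians of finite posterior samples
                if rec.s_median > parent.s_median * (1 + 1e-9):
                    raise ValueError(
                        f"node {rec.node_id}: s median {rec.s_median} exceeds "
                        f"parent {parent.node_id}'s {parent.s_median}"
                    )
        if self.tree is not None:
            node_heights(self.tree)  # raises if not ultrametric

    def _nearest_dated_ancestor(self, rec: NodeRecord) -> Optional[NodeRecord]:
        cur = rec
        while cur.parent_id is not None:
            cur = self.nodes[cur.parent_id]
            if cur.is_dated:
                return cur
        return None

    @property
    def dated_ids(self) -> List[str]:
        """Dated node ids, root-to-tip (parents before children)."""
        order: List[str] = []

        def walk(nid: str) -> None:
            if self.nodes[nid].is_dated:
                order.append(nid)
            for child in self._children(nid):
                walk(child)

        root = next(r.node_id for r in self.nodes.values() if r.parent_id is None)
        walk(root)
        return order

    @property
    def undated_ids(self) -> List[str]:
        return [nid for nid, r in self.nodes.items() if not r.is_dated]

    def _children(self, nid: str) -> List[str]:
        return [r.node_id for r in self.nodes.values() if r.parent_id == nid]

    def dated_parent_index(self) -> Dict[str, Optional[str]]:
        """Per dated node, its nearest dated ancestor (None for the deepest)."""
        out: Dict[str, Optional[str]] = {}
        for nid in self.dated_ids:
            anc = self._nearest_dated_ancestor(self.nodes[nid])
            out[nid] = anc.node_id if anc is not None else None
        return out

    def subset(self, node_ids: Sequence[str]) -> "CospeciationDataset":
        """Dataset restricted to ``node_ids``, re-rooting parent links past
        removed nodes (tree not carried over)."""
        keep = set(node_ids)
        recs = []
        for nid in node_ids:
            rec = self.nodes[nid]
            pid = rec.parent_id
            while pid is not None and pid not in keep:
                pid = self.nodes[pid].parent_id
            recs.append(
                NodeRecord(
                    node_id=rec.node_id,
                    parent_id=pid,
                    s_samples=rec.s_samples,
                    calibration=rec.calibration,
                    s_reconstructed=rec.s_reconstructed,
                )
            )
        return CospeciationDataset(recs)


@dataclass(frozen=True)
class RateSampleSet:
    """One resampled pairing of (t, s, rbar) across dated nodes.

    t is in Myr, s in substitutions/site, rbar = s / (t * 1e6) in
    substitutions/site/year.
    """

    node_ids: tuple
    t_myr: np.ndarray
    s: np.ndarray
    rbar_per_year: np.ndarray

    @classmethod
    def from_ts(cls, node_ids: Sequence[str], t_myr, s) -> "RateSampleSet":
        t_myr = np.asarray(t_myr, dtype=float)
        s = np.asarray(s, dtype=float)
        if not (len(node_ids) == t_myr.size == s.size):
            raise ValueError("node_ids, t and s must have equal length")
        if np.any(t_myr <= 0) or np.any(s <= 0):
            raise ValueError("t and s must be positive")
        return cls(
            node_ids=tuple(node_ids),
            t_myr=t_myr,
            s=s,
            rbar_per_year=s / (t_myr * YEARS_PER_MYR),
        )

    def __len__(self) -> int:
        return len(self.node_ids)

    def drop(self, index: int) -> "RateSampleSet":
        keep = np.arange(len(self)) != index
        return RateSampleSet(
            node_ids=tuple(np.asarray(self.node_ids)[keep]),
            t_myr=self.t_myr[keep],
            s=self.s[keep],
            rbar_per_year=self.rbar_per_year[keep],
        )


# ---------------------------------------------------------------------------
# tree heights


def node_heights(tree: dendropy.Tree) -> Dict[str, float]:
    """Node-to-tip path length (substitutions/site) per labelled internal node.

    The tree must be ultrametric: for each internal node, all descendant
    tips must be equidistant within ``1e-6 * max(height, 1)``; the returned
    height is the mean tip distance.
    """
    heights: Dict[str, float] = {}
    # distance from each node down to each descendant leaf
    for nd in tree.postorder_node_iter():
        if nd.is_leaf():
            nd._tip_dists = [0.0]
        else:
            dists = []
            for ch in nd.child_nodes():
                if ch.edge.length is None:
                    raise ValueError(
                        f"missing branch length above {ch.taxon or ch.label}"
                    )
                dists.extend(d + ch.edge.length for d in ch._tip_dists)
            nd._tip_dists = dists
            h = float(np.mean(dists))
            spread = max(dists) - min(dists)
            if spread > 1e-6 * max(h, 1.0):
                raise ValueError(
                    f"tree is not ultrametric at node {nd.label!r}: tip "
                    f"distances span {spread:g} (height {h:g})"
                )
            label = nd.label
            if label:
                heights[str(label)] = h
    for nd in tree.preorder_node_iter():
        if hasattr(nd, "_tip_dists"):
            del nd._tip_dists
    return heights


# ---------------------------------------------------------------------------
# resampling


class SimulationFailure(RuntimeError):
    """Ordering-constrained time simulation exceeded the attempt cap."""


def simulate_calibration_times(
    dataset: CospeciationDataset,
    n_sets: int,
    seed,
) -> Dict[str, np.ndarray]:
    """Draw ``n_sets`` joint node-age vectors (Myr) from the calibration priors.

    Each dated node's age is normal (mean = prior median, sd = prior sd)
    constrained so that every child's draw is below its nearest dated
    ancestor's, row by row.  Sampling is top-down: parents first, children
    by rejection from the parent-truncated normal (cap 1,000 attempts per
    node per row; exceeding it raises :class:`SimulationFailure`).  Draws
    are truncated below at 1e-6 Myr.
    """
    if n_sets < 1:
        raise ValueError("n_sets must be >= 1")
    rng = np.random.default_rng(seed)
    parent_of = dataset.dated_parent_index()
    draws: Dict[str, np.ndarray] = {}
    for nid in dataset.dated_ids:  # root-to-tip order
        prior = dataset.nodes[nid].calibration
        upper = (
            draws[parent_of[nid]]
            if parent_of[nid] is not None
            else np.full(n_sets, np.inf)
        )
        vals = np.full(n_sets, np.nan)
        pending = np.ones(n_sets, dtype=bool)
        for _ in range(MAX_ATTEMPTS):
            n_pend = int(pending.sum())
            if n_pend == 0:
                break
            cand = prior.median + prior.sd * rng.standard_normal(n_pend)
            ok = (cand > MIN_TIME_MYR) & (cand < upper[pending])
            idx = np.flatnonzero(pending)
            vals[idx[ok]] = cand[ok]
            pending[idx[ok]] = False
            if prior.sd == 0.0:
                # degenerate prior: either feasible everywhere or never
                break
        if pending.any():
            raise SimulationFailure(
                f"node {nid}: could not draw an age below its dated ancestor "
                f"within {MAX_ATTEMPTS} attempts for {int(pending.sum())} rows "
                "(ordering likely infeasible given the priors)"
            )
        draws[nid] = vals
    return draws


def assemble_rate_sets(
    dataset: CospeciationDataset,
    n_sets: int,
    seed,
) -> List[RateSampleSet]:
    """Build ``n_sets`` resampled (t, s, rbar) sets over the dated nodes.

    For each set, one simulated joint age vector is paired with one
    posterior s sub-dataset: a single posterior index drawn uniformly and
    shared across nodes, so each set's s values come from one coherent
    posterior sample of the substitution-unit tree.
    """
    if n_sets < 1:
        raise ValueError("n_sets must be >= 1")
    ss = np.random.SeedSequence(_entropy(seed))
    t_seed, s_seed = ss.spawn(2)
    t_draws = simulate_calibration_times(dataset, n_sets, t_seed)
    rng = np.random.default_rng(s_seed)
    ids = dataset.dated_ids
    n_draws = min(dataset.nodes[nid].s_samples.size for nid in ids)
    idx = rng.integers(0, n_draws, size=n_sets)
    sets = []
    for m in range(n_sets):
        t = np.array([t_draws[nid][m] for nid in ids])
        s = np.array([dataset.nodes[nid].s_samples[idx[m]] for nid in ids])
        sets.append(RateSampleSet.from_ts(ids, t, s))
    return sets


def _entropy(seed):
    """Accept ints, SeedSequences or Generators uniformly."""
    if isinstance(seed, np.random.SeedSequence):
        return seed
    if isinstance(seed, np.random.Generator):
        return seed.integers(0, 2**31 - 1)
    return seed


def posterior_index_draws(dataset, n_sets: int, seed) -> np.ndarray:
    """The shared posterior indices assemble_rate_sets would use (for
    co-sampling s of undated nodes with the dated-node sets)."""
    ss = np.random.SeedSequence(_entropy(seed))
    _, s_seed = ss.spawn(2)
    rng = np.random.default_rng(s_seed)
    ids = dataset.dated_ids
    n_draws = min(dataset.nodes[nid].s_samples.size for nid in ids)
    return rng.integers(0, n_draws, size=n_sets)
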