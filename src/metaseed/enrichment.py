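"""Metabolite-set enrichment (MSEA), correlation clustering, and the
relative-quantification helper for qRT-PCR validation.

MSEA mirrors gene-set enrichment analysis: retained LC-MS features form
the reference metabolome, ranked by a differential metric; each pathway's
metabolite set is tested with an unweighted Kolmogorov-Smirnov running
sum. Walking the ranking, the sum gains 1/H at a set member and loses
1/(N-H) elsewhere; the enrichment score ES is the signed maximal
excursion (ES = +1 iff the members fill a prefix). Significance comes
from placing the H members uniformly at random among the N ranks —
enumerated exhaustively when feasible, Monte Carlo otherwise — with
Benjamini-Hochberg adjustment across sets.
"""

from __future__ import annotations

import itertools
import logging
import math
import warnings
import zlib
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from statsmodels.stats.multitest import multipletests

from .annotation import MetaboliteSet
from .preprocess import RETAINED, FeatureRecord

logger = logging.getLogger(__name__)

__all__ = [
    "RankedList",
    "EnrichmentResult",
    "PfafflInput",
    "rank_features",
    "ks_enrichment",
    "permutation_pvalue",
    "msea",
    "correlation_clustering",
    "linkage_to_newick",
    "pfaffl_fold_change",
]


@dataclass(frozen=True)
class RankedList:
    """Feature ids in descending score order (ties broken by id)."""

    ids: Tuple[str, ...]
    scores: Mapping[str, float]

    def __len__(self) -> int:
        return len(self.ids)

    def positions(self, members: Iterable[str]) -> np.ndarray:
        index = {fid: i for i, fid in enumerate(self.ids)}
        return np.array(sorted(index[m] for m in members), dtype=np.int64)


@dataclass(frozen=True)
class EnrichmentResult:
    pathway_id: str
    es: float
    p_value: float
    q_value: float
    n_members: int
    direction: str  # up | down
    active: bool


def rank_features(
    features: Sequence[FeatureRecord],
    metric: str = "signed_percent_change",
) -> RankedList:
    """Build the reference-metabolome ranking over retained features.

    ``signed_percent_change`` ranks by the percent abundance change (an
    undefined change with a +inf fold sentinel sorts to the top);
    ``t_statistic`` ranks by the Welch t statistic.
    """
    retained = [f for f in features if f.status == RETAINED]
    scores: Dict[str, float] = {}
    offenders: List[str] = []
    for f in retained:
        if metric == "signed_percent_change":
            if f.percent_change is not None:
                s = f.percent_change
            elif f.fold_change is not None and math.isinf(f.fold_change):
                s = math.inf if f.fold_change > 0 else -math.inf
            else:
                s = math.nan
        elif metric == "t_statistic":
            s = f.t_stat if getattr(f, "t_stat", None) is not None else math.nan
        else:
            raise ValueError(f"unknown ranking metric {metric!r}")
        if math.isnan(s):
            offenders.append(f.peak_id)
        scores[f.peak_id] = s
    if offenders:
        raise ValueError(f"NaN ranking scores for features: {offenders}")
    ordered = sorted(scores, key=lambda fid: (-scores[fid], fid))
    return RankedList(tuple(ordered), scores)


def _es_from_positions(positions: np.ndarray, n: int) -> float:
    """ES from sorted 0-based member positions in a ranking of length n.

    The running sum peaks immediately after a member and bottoms out
    immediately before one, so only those 2H values need inspection.
    On an exact |max| == |min| tie the positive excursion is reported.
    """
    h = len(positions)
    if not 0 < h < n:
        raise ValueError(f"need 0 < H < N, got H={h}, N={n}")
    i = np.arange(1, h + 1)
    misses_before = positions - (i - 1)
    after_hit = i / h - misses_before / (n - h)
    before_hit = (i - 1) / h - misses_before / (n - h)
    top = float(after_hit.max())
    bottom = float(before_hit.min())
    return top if abs(top) >= abs(bottom) - 1e-12 else bottom


def ks_enrichment(ranked: RankedList | Sequence[str],
                  member_ids: Iterable[str] | MetaboliteSet) -> float:
    """Signed maximal excursion of the KS running sum for one set."""
    if isinstance(member_ids, MetaboliteSet):
        member_ids = member_ids.members.keys()
    ids = ranked.ids if isinstance(ranked, RankedList) else tuple(ranked)
    members = set(member_ids)
    n, h = len(ids), len(members)
    if h == 0 or h >= n:
        raise ValueError(f"need 0 < H < N, got H={h}, N={n}")
    unknown = members - set(ids)
    if unknown:
        raise ValueError(f"set members missing from ranking: {sorted(unknown)}")
    positions = np.array(sorted(i for i, fid in enumerate(ids) if fid in members),
                         dtype=np.int64)
    return _es_from_positions(positions, n)


def _null_es(n: int, h: int, n_perm: int, rng: np.random.Generator,
             chunk_elems: int = 2_000_000) -> np.ndarray:
    """Monte-Carlo null: ES of h uniform random positions among n ranks."""
    out = np.empty(n_perm)
    done = 0
    chunk = max(1, chunk_elems // n)
    i_idx = np.arange(1, h + 1)
    while done < n_perm:
        k = min(chunk, n_perm - done)
        u = rng.random((k, n))
        pos = np.sort(np.argpartition(u, h - 1, axis=1)[:, :h], axis=1)
        misses = pos - (i_idx - 1)
        after = i_idx / h - misses / (n - h)
        before = (i_idx - 1) / h - misses / (n - h)
        top = after.max(axis=1)
        bottom = before.min(axis=1)
        out[done:done + k] = np.where(np.abs(top) >= np.abs(bottom) - 1e-12,
                                      top, bottom)
        done += k
    return out


def permutation_pvalue(
    ranked: RankedList | Sequence[str],
    member_ids: Iterable[str] | MetaboliteSet,
    n_perm: int = 10000,
    seed: int = 0,
    exhaustive_limit: int = 10000,
) -> float:
    """Two-sided permutation p-value for a set's |ES|.

    When C(N, H) <= ``exhaustive_limit`` every placement of the members
    is enumerated and p is the exact null fraction with |ES| >= |ES_obs|;
    otherwise ``n_perm`` Monte-Carlo placements are drawn and p uses the
    standard +1 pseudo-count.
    """
    if isinstance(member_ids, MetaboliteSet):
        member_ids = list(member_ids.members.keys())
    ids = ranked.ids if isinstance(ranked, RankedList) else tuple(ranked)
    members = list(member_ids)
    n, h = len(ids), len(members)
    es_obs = ks_enrichment(ids, members)

    if math.comb(n, h) <= exhaustive_limit:
        count = 0
        total = 0
        for combo in itertools.combinations(range(n), h):
            es = _es_from_positions(np.array(combo, dtype=np.int64), n)
            count += abs(es) >= abs(es_obs) - 1e-12
            total += 1
        return count / total

    if n_perm < 100:
        raise ValueError("n_perm must be at least 100")
    rng = np.random.default_rng(seed)
    null = _null_es(n, h, n_perm, rng)
    exceed = int((np.abs(null) >= abs(es_obs) - 1e-12).sum())
    return (1 + exceed) / (1 + n_perm)


def _substream_seed(seed: int, pathway_id: str) -> int:
    # keyed by pathway id so set iteration order cannot change p-values
    return (seed ^ zlib.crc32(pathway_id.encode())) & 0x7FFFFFFF


def msea(
    ranked: RankedList,
    sets: Mapping[str, MetaboliteSet] | Mapping[str, Iterable[str]],
    n_perm: int = 10000,
    seed: int = 0,
    alpha: float = 0.05,
    use_q_value: bool = True,
) -> List[EnrichmentResult]:
    """ES + permutation p per metabolite set, BH-adjusted across sets.

    Sets whose members are not all present in the ranking are restricted
    to the ranked subset (features eliminated upstream cannot carry
    signal). Results are sorted by p, then pathway id; ``active`` flags
    q <= alpha (or raw p <= alpha with ``use_q_value=False``).
    """
    rows = []
    ranked_ids = set(ranked.ids)
    for pid in sorted(sets):
        s = sets[pid]
        members = set(s.members.keys() if isinstance(s, MetaboliteSet) else s)
        members &= ranked_ids
        if not 0 < len(members) < len(ranked):
            logger.warning("skipping set %s: %d usable members of %d ranked",
                           pid, len(members), len(ranked))
            continue
        es = ks_enrichment(ranked, members)
        p = permutation_pvalue(ranked, members, n_perm=n_perm,
                               seed=_substream_seed(seed, pid))
        rows.append((pid, es, p, len(members)))
    if not rows:
        return []
    pvals = [r[2] for r in rows]
    _rej, qvals, *_ = multipletests(pvals, method="fdr_bh")
    results = []
    for (pid, es, p, n_mem), q in zip(rows, qvals):
        crit = q if use_q_value else p
        results.append(EnrichmentResult(
            pid, es, p, float(q), n_mem,
            direction="up" if es >= 0 else "down",
            active=bool(crit <= alpha),
        ))
    results.sort(key=lambda r: (r.p_value, r.pathway_id))
    return results


def correlation_clustering(
    vectors: Mapping[str, Sequence[float]] | pd.DataFrame,
) -> Tuple[pd.DataFrame, np.ndarray, List[str]]:
    """Pearson-correlation structure of per-feature change profiles.

    Rows are features, columns observations (timepoints x conditions).
    Zero-variance profiles are excluded with a warning (their correlation
    is undefined). Returns (r matrix, average-linkage tree on distance
    1 - r, leaf order). Requires >= 2 usable features and >= 2
    observations.
    """
    df = pd.DataFrame(vectors).T if not isinstance(vectors, pd.DataFrame) else vectors
    if df.shape[1] < 2:
        raise ValueError("need at least 2 observations per feature")
    variances = df.var(axis=1, ddof=0)
    degenerate = list(df.index[variances == 0])
    if degenerate:
        warnings.warn(f"excluding zero-variance profiles: {degenerate}")
        df = df.drop(index=degenerate)
    if df.shape[0] < 2:
        raise ValueError("need at least 2 features with non-zero variance")

    r = pd.DataFrame(np.corrcoef(df.to_numpy()), index=df.index, columns=df.index)
    dist = 1.0 - r.to_numpy()
    np.fill_diagonal(dist, 0.0)
    condensed = dist[np.triu_indices_from(dist, k=1)]
    linkage = hierarchy.linkage(np.clip(condensed, 0.0, None), method="average")
    leaves = hierarchy.leaves_list(linkage)
    return r, linkage, [str(df.index[i]) for i in leaves]


def linkage_to_newick(linkage: np.ndarray, labels: Sequence[str]) -> str:
    """Render a scipy linkage matrix as a Newick tree with branch lengths."""
    tree = hierarchy.to_tree(linkage)

    def walk(node, parent_height: float) -> str:
        length = parent_height - (0.0 if node.is_leaf() else node.dist)
        if node.is_leaf():
            return f"{labels[node.id]}:{parent_height:.6g}"
        left = walk(node.left, node.dist)
        right = walk(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    return f"({walk(tree.left, tree.dist)},{walk(tree.right, tree.dist)});"


@dataclass(frozen=True)
class PfafflInput:
    """Crossing points and amplification efficiencies for one transcript
    pair. Efficiencies are fold-per-cycle in (1, 2]; delta-Cp values are
    control minus treated, in cycles."""

    eff_target: float
    eff_housekeeping: float
    dcp_target: float
    dcp_housekeeping: float

    def __post_init__(self) -> None:
        for name, eff in (("eff_target", self.eff_target),
                          ("eff_housekeeping", self.eff_housekeeping)):
            if not 1.0 < eff <= 2.0:
                raise ValueError(f"{name} must be in (1, 2], got {eff}")


def pfaffl_fold_change(inp: PfafflInput) -> float:
    """Relative expression ratio: Eff_t^dCp_t / Eff_h^dCp_h."""
    return (inp.eff_target ** inp.dcp_target
            / inp.eff_housekeeping ** inp.dcp_housekeeping)
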