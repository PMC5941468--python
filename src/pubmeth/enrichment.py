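"""Gene-set over-representation: permutation test plus exact oracles.

Two resampling frames are provided.  ``literal`` mode draws the observed
list's size from the estrogen-responsive gene set itself and counts overlap
with the observed list — the procedure exactly as the source analysis
describes it.  ``universe`` mode draws from the full gene universe and
counts in-set members, which is the conventional null matching a 2x2
contingency layout; its permutation p converges to the exact
hypergeometric tail.  The two can give very different p-values; both are
exposed and the mode is recorded in the result.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import stats


class EnrichmentError(ValueError):
    pass


def normalize_genes(genes: Iterable[str]) -> list[str]:
    """Uppercase ids, preserve first-seen order, drop duplicates."""
    seen: dict[str, None] = {}
    for g in genes:
        seen.setdefault(str(g).upper(), None)
    return list(seen)


@dataclass
class ContingencyTable:
    """2x2 counts: rows observed/not-observed, columns in-set/out-of-set."""

    a: int  # observed & in set
    b: int  # observed & out of set
    c: int  # not observed & in set
    d: int  # not observed & out of set

    @property
    def k_obs(self) -> int:
        return self.a + self.b

    @property
    def set_size(self) -> int:
        return self.a + self.c

    @property
    def universe_size(self) -> int:
        return self.a + self.b + self.c + self.d

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]])

    def row_percent_in_set(self) -> float:
        """In-set percentage among observed genes, one decimal."""
        return round(100.0 * self.a / self.k_obs, 1)


def build_contingency(
    observed: Sequence[str], er_set: Iterable[str], universe: Sequence[str]
) -> ContingencyTable:
    obs = set(normalize_genes(observed))
    gs = set(normalize_genes(er_set))
    uni = set(normalize_genes(universe))
    outside = sorted(obs - uni)
    if outside:
        raise EnrichmentError(f"observed genes outside universe: {outside[:10]}")
    gs &= uni
    a = len(obs & gs)
    b = len(obs - gs)
    c = len(gs - obs)
    d = len(uni - gs - obs)
    return ContingencyTable(a, b, c, d)


def hypergeom_tail(x_obs: int, set_size: int, k_obs: int, universe_size: int) -> float:
    """Exact upper tail P(X >= x_obs) for X ~ Hypergeom(N, K, n)."""
    if not (0 <= set_size <= universe_size and 0 <= k_obs <= universe_size):
        raise EnrichmentError("inconsistent counts")
    if x_obs < 0 or x_obs > min(set_size, k_obs) + 1:
        raise EnrichmentError("x_obs out of range")
    return float(stats.hypergeom.sf(x_obs - 1, universe_size, set_size, k_obs))


def fisher_exact(table: ContingencyTable | np.ndarray, alternative: str = "two-sided"):
    """Conditional exact test; ``alternative='greater'`` gives the
    right-tailed form.  Returns (odds_ratio, p); odds ratio is NaN when a
    margin is zero."""
    arr = table.as_array() if isinstance(table, ContingencyTable) else np.asarray(table)
    if (arr < 0).any() or not np.issubdtype(arr.dtype, np.integer):
        arr = arr.astype(int)
        if (arr < 0).any():
            raise EnrichmentError("cells must be nonnegative integers")
    odds, p = stats.fisher_exact(arr, alternative=alternative)
    if min(arr.sum(axis=0).min(), arr.sum(axis=1).min()) == 0:
        odds = float("nan")
    return float(odds), float(p)


@dataclass
class EnrichmentResult:
    name: str
    mode: str
    k_obs: int
    x_obs: int
    set_size: int
    universe_size: int
    table: ContingencyTable
    n_perm: int
    r: int  # permutations with overlap >= x_obs
    p_perm: float  # (r + 1) / (n_perm + 1)
    p_bound: float | None  # 1/n_perm bound when r == 0, else None
    bound_str: str | None
    p_hypergeom: float
    fisher_odds: float
    fisher_p: float
    seed: int | None

    @property
    def p_reported(self) -> float:
        """The bound when no permutation reached the observed overlap,
        otherwise the add-one permutation estimate."""
        return self.p_bound if self.p_bound is not None else self.p_perm

    def to_dict(self) -> dict:
        d = {k: getattr(self, k) for k in (
            "name", "mode", "k_obs", "x_obs", "set_size", "universe_size",
            "n_perm", "r", "p_perm", "p_bound", "bound_str",
            "p_hypergeom", "fisher_odds", "fisher_p", "seed",
        )}
        t = self.table
        d["table"] = {"a": t.a, "b": t.b, "c": t.c, "d": t.d}
        d["pct_in_set"] = t.row_percent_in_set()
        return d


def _count_overlaps(
    pool_size: int,
    draw: int,
    mask: np.ndarray,
    n_perm: int,
    rng: np.random.Generator,
    chunk_bytes: int = 64 * 2**20,
) -> np.ndarray:
    """Overlap counts for uniform without-replacement draws from a pool.

    Each iteration selects ``draw`` distinct pool indices via the smallest
    ``draw`` of i.i.d. uniform keys (an exact uniform subset sampler) and
    counts how many fall in ``mask``; done in chunks to bound memory.
    """
    chunk = max(1, min(n_perm, chunk_bytes // (8 * pool_size)))
    out = np.empty(n_perm, dtype=np.int64)
    done = 0
    while done < n_perm:
        c = min(chunk, n_perm - done)
        keys = rng.random((c, pool_size))
        idx = np.argpartition(keys, draw - 1, axis=1)[:, :draw]
        out[done : done + c] = mask[idx].sum(axis=1)
        done += c
    return out


def permutation_enrichment(
    observed: Sequence[str],
    er_set: Iterable[str],
    universe: Sequence[str],
    n_perm: int = 500_000,
    mode: str = "literal",
    seed: int | None = None,
    name: str = "enrichment",
) -> EnrichmentResult:
    """Permutation over-representation test of ``observed`` against a gene set.

    literal mode draws |observed| genes from the set and scores overlap with
    the observed list; universe mode draws |observed| genes from the
    universe and scores set membership.  The exceedance count r tallies
    draws with statistic >= x_obs; p = (r+1)/(n_perm+1), with the
    ``< 1/n_perm`` bound reported when r = 0.
    """
    if n_perm < 1:
        raise EnrichmentError("n_perm must be >= 1")
    if mode not in {"literal", "universe"}:
        raise EnrichmentError(f"unknown mode {mode!r}")
    obs = normalize_genes(observed)
    gs = normalize_genes(er_set)
    uni = normalize_genes(universe)
    table = build_contingency(obs, gs, uni)
    x_obs, k_obs = table.a, table.k_obs
    if x_obs > k_obs:
        raise EnrichmentError("x_obs exceeds observed list size")
    rng = np.random.default_rng(seed)
    if mode == "literal":
        pool = gs
        if len(pool) < k_obs:
            raise EnrichmentError(
                f"literal mode needs set size >= draw size ({len(pool)} < {k_obs})"
            )
        obs_set = set(obs)
        mask = np.fromiter((g in obs_set for g in pool), dtype=bool, count=len(pool))
    else:
        pool = uni
        gs_set = set(gs)
        mask = np.fromiter((g in gs_set for g in pool), dtype=bool, count=len(pool))
    counts = _count_overlaps(len(pool), k_obs, mask, n_perm, rng)
    r = int((counts >= x_obs).sum())
    p_perm = (r + 1) / (n_perm + 1)
    p_bound = 1.0 / n_perm if r == 0 else None
    bound_str = f"< {1.0 / n_perm:.1e}" if r == 0 else None
    p_hg = hypergeom_tail(x_obs, table.set_size, k_obs, table.universe_size)
    odds, fp = fisher_exact(table, alternative="greater")
    return EnrichmentResult(
        name=name,
        mode=mode,
        k_obs=k_obs,
        x_obs=x_obs,
        set_size=table.set_size,
        universe_size=table.universe_size,
        table=table,
        n_perm=n_perm,
        r=r,
        p_perm=p_perm,
        p_bound=p_bound,
        bound_str=bound_str,
        p_hypergeom=p_hg,
        fisher_odds=odds,
        fisher_p=fp,
        seed=seed,
    )
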