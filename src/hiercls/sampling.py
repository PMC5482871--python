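"""Quadruplet mining and hierarchy-aware mini-batch composition.

The miner turns a labelled mini-batch into (anchor, same-subclass positive,
same-superclass positive, cross-superclass negative) index tuples; the batch
sampler composes batches that make such tuples likely to exist.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from hiercls.hierarchy import PairRelation, Taxonomy, relation

__all__ = ["Quadruplet", "mine_quadruplets", "enumerate_quadruplets", "hierarchy_balanced_batch"]


@dataclass(frozen=True)
class Quadruplet:
    """Index tuple into a mini-batch: anchor, same-subclass positive,
    same-superclass/different-subclass positive, cross-superclass negative."""

    anchor: int
    pos_same_sub: int
    pos_same_super: int
    neg: int

    def as_tuple(self) -> tuple[int, int, int, int]:
        return (self.anchor, self.pos_same_sub, self.pos_same_super, self.neg)


def _partition_partners(
    labels: Sequence[str], t: Taxonomy
) -> tuple[list[str], dict[str, list[int]], dict[str, list[int]], dict[str, list[int]]]:
    """Per-label index lists for the three partner roles."""
    canon = [t.canonical(l) for l in labels]
    by_sub: dict[str, list[int]] = {}
    for i, c in enumerate(canon):
        by_sub.setdefault(c, []).append(i)
    same_sub = {c: idxs for c, idxs in by_sub.items()}
    same_super: dict[str, list[int]] = {}
    cross_super: dict[str, list[int]] = {}
    for c in by_sub:
        sup = t.subclass_map[c]
        same_super[c] = [
            i for d, idxs in by_sub.items() if d != c and t.subclass_map[d] == sup for i in idxs
        ]
        cross_super[c] = [
            i for d, idxs in by_sub.items() if t.subclass_map[d] != sup for i in idxs
        ]
    return canon, same_sub, same_super, cross_super


def enumerate_quadruplets(labels: Sequence[str], t: Taxonomy) -> list[Quadruplet]:
    """Exhaustively enumerate every valid quadruplet in a batch (oracle for
    the miner; quadratic-ish, for small batches and tests)."""
    canon, same_sub, same_super, cross_super = _partition_partners(labels, t)
    out = []
    for a, c in enumerate(canon):
        for pp in same_sub[c]:
            if pp == a:
                continue
            for pm in same_super[c]:
                for n in cross_super[c]:
                    out.append(Quadruplet(a, pp, pm, n))
    return out


def mine_quadruplets(
    labels: Sequence[str],
    t: Taxonomy,
    per_anchor: int = 1,
    rng_seed: int = 0,
) -> list[Quadruplet]:
    """Sample valid quadruplets from a labelled batch.

    For each anchor with at least one partner in each of the three roles
    (same subclass, sibling subclass, other superclass), draws up to
    ``per_anchor`` tuples of random eligible partners.  Deterministic for a
    given ``rng_seed``.  Anchors lacking a partner role contribute nothing;
    a batch with no eligible anchor returns an empty list with a warning
    (the training step then falls back to the softmax term alone).
    """
    if len(labels) < 4:
        raise ValueError(f"need at least 4 labels to mine quadruplets, got {len(labels)}")
    if per_anchor < 1:
        raise ValueError("per_anchor must be >= 1")
    rng = np.random.default_rng(rng_seed)
    canon, same_sub, same_super, cross_super = _partition_partners(labels, t)
    out: list[Quadruplet] = []
    for a, c in enumerate(canon):
        pp_pool = [i for i in same_sub[c] if i != a]
        pm_pool = same_super[c]
        n_pool = cross_super[c]
        if not (pp_pool and pm_pool and n_pool):
            continue
        for _ in range(per_anchor):
            out.append(
                Quadruplet(
                    a,
                    int(rng.choice(pp_pool)),
                    int(rng.choice(pm_pool)),
                    int(rng.choice(n_pool)),
                )
            )
    if not out:
        warnings.warn(
            "no quadruplet-eligible anchors in batch; falling back to softmax-only step",
            stacklevel=2,
        )
    # drop duplicates introduced by per_anchor > pool sizes
    seen: set[tuple[int, int, int, int]] = set()
    unique = []
    for q in out:
        if q.as_tuple() not in seen:
            seen.add(q.as_tuple())
            unique.append(q)
    return unique


def hierarchy_balanced_batch(
    labels: Sequence[str],
    t: Taxonomy,
    batch_size: int,
    rng_seed: int = 0,
    policy: str = "stratified",
) -> list[int]:
    """Compose a mini-batch (list of indices into *labels*) guaranteed to be
    quadruplet-feasible.

    The batch contains at least two images of some subclass, at least one of
    a sibling subclass and at least one from the other superclass.  Under
    the default ``stratified`` policy, slots are spread round-robin over the
    subclasses present, so on a balanced manifest with ``batch_size >= 2k``
    every subclass appears at least twice.
    """
    if batch_size < 8:
        raise ValueError("batch_size must be >= 8")
    canon = [t.canonical(l) for l in labels]
    by_sub: dict[str, list[int]] = {}
    for i, c in enumerate(canon):
        by_sub.setdefault(c, []).append(i)
    supers_present = {t.subclass_map[c] for c in by_sub}
    feasible = any(
        len(idxs) >= 2
        and any(t.subclass_map[d] == t.subclass_map[c] and d != c for d in by_sub)
        for c, idxs in by_sub.items()
    ) and len(supers_present) >= 2
    if not feasible:
        raise ValueError(
            "manifest cannot form quadruplets: need >=2 images of one subclass, "
            "a sibling subclass, and both superclasses present"
        )
    if policy != "stratified":
        raise ValueError(f"unknown batch policy: {policy!r}")
    rng = np.random.default_rng(rng_seed)
    pools = {c: rng.permutation(idxs).tolist() for c, idxs in by_sub.items()}
    order = sorted(pools)
    batch: list[int] = []
    # round-robin over subclasses, without replacement while pools last
    exhausted: set[str] = set()
    while len(batch) < batch_size:
        progressed = False
        for c in order:
            if len(batch) >= batch_size:
                break
            if pools[c]:
                batch.append(pools[c].pop())
                progressed = True
            else:
                exhausted.add(c)
        if not progressed:
            # all pools empty: re-fill (sampling with replacement across epochs)
            pools = {c: rng.permutation(by_sub[c]).tolist() for c in by_sub}
    # ensure feasibility of the drawn batch; if round-robin under-sampled a
    # needed role (tiny batch_size), swap the last slots
    if not _batch_feasible(batch, canon, t):
        batch = _repair_batch(batch, canon, by_sub, t, rng)
    return batch


def _batch_feasible(batch: list[int], canon: list[str], t: Taxonomy) -> bool:
    from collections import Counter

    cnt = Counter(canon[i] for i in batch)
    for c, n in cnt.items():
        if n >= 2:
            sup = t.subclass_map[c]
            has_sib = any(t.subclass_map[d] == sup and d != c for d in cnt)
            has_neg = any(t.subclass_map[d] != sup for d in cnt)
            if has_sib and has_neg:
                return True
    return False


def _repair_batch(batch, canon, by_sub, t, rng):
    """Replace trailing slots to guarantee a feasible composition."""
    # pick a subclass with >=2 images and a sibling present in the manifest
    for c, idxs in sorted(by_sub.items()):
        sibs = [d for d in by_sub if d != c and t.subclass_map[d] == t.subclass_map[c]]
        negs = [d for d in by_sub if t.subclass_map[d] != t.subclass_map[c]]
        if len(idxs) >= 2 and sibs and negs:
            forced = [
                int(rng.choice(by_sub[c])),
                int(rng.choice([i for i in by_sub[c]])),
                int(rng.choice(by_sub[sibs[0]])),
                int(rng.choice(by_sub[negs[0]])),
            ]
            # make anchor pair distinct where possible
            if forced[0] == forced[1] and len(by_sub[c]) > 1:
                forced[1] = int(rng.choice([i for i in by_sub[c] if i != forced[0]]))
            return forced + batch[: len(batch) - 4]
    raise ValueError("batch repair failed: manifest not quadruplet-feasible")
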