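"""Integer-indexed reaction-network view and JIT-compiled closure kernels.

The public :class:`~rafkit.crs.CRS` stores reactions by string id; the
algorithms run on a compressed-sparse-row (CSR) view built once per CRS.
Reversible reactions contribute two *directions*; each direction has a
deduplicated reactant list and a product list.  The food-set closure is a
standard counting fixpoint: each direction keeps a count of reactants not yet
in the closure, and fires when it reaches zero.

The pruning kernel implements the bookkeeping of the pRAF-accelerated maximum
RAF algorithm: per-molecule counts of "active" producing reactions (reactions
fired during the last closure) are decremented as reactions are discarded, and
removals cascade without recomputing the closure.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["ReactionNetwork"]


@njit(cache=True)
def _closure_kernel(
    active,
    dir_ent,
    dir_r_ptr,
    dir_r_idx,
    dir_p_ptr,
    dir_p_idx,
    mol_dir_ptr,
    mol_dir_idx,
    food_idx,
    n_mol,
):
    n_dir = dir_ent.size
    need = np.full(n_dir, -1, np.int32)
    in_cl = np.zeros(n_mol, np.bool_)
    fired = np.zeros(n_dir, np.bool_)
    prod_count = np.zeros(n_mol, np.int32)
    stack = np.empty(n_mol, np.int64)
    top = 0
    for d in range(n_dir):
        if active[dir_ent[d]]:
            need[d] = dir_r_ptr[d + 1] - dir_r_ptr[d]
    for i in range(food_idx.size):
        x = food_idx[i]
        if not in_cl[x]:
            in_cl[x] = True
            stack[top] = x
            top += 1
    while top > 0:
        top -= 1
        x = stack[top]
        for k in range(mol_dir_ptr[x], mol_dir_ptr[x + 1]):
            d = mol_dir_idx[k]
            if need[d] > 0:
                need[d] -= 1
                if need[d] == 0:
                    fired[d] = True
                    for j in range(dir_p_ptr[d], dir_p_ptr[d + 1]):
                        p = dir_p_idx[j]
                        prod_count[p] += 1
                        if not in_cl[p]:
                            in_cl[p] = True
                            stack[top] = p
                            top += 1
    return in_cl, fired, prod_count


@njit(cache=True)
def _filter_f_kernel(active, in_cl, fired, dir_ent, ent_dir_ptr, ent_dir_idx, cat_ptr, cat_idx):
    """One application of f given a computed closure: keep reactions with a
    fired direction and a catalyst inside the closure."""
    n_ent = active.size
    keep = np.zeros(n_ent, np.bool_)
    for r in range(n_ent):
        if not active[r]:
            continue
        ok_dir = False
        for k in range(ent_dir_ptr[r], ent_dir_ptr[r + 1]):
            if fired[ent_dir_idx[k]]:
                ok_dir = True
                break
        if not ok_dir:
            continue
        for k in range(cat_ptr[r], cat_ptr[r + 1]):
            if in_cl[cat_idx[k]]:
                keep[r] = True
                break
    return keep


@njit(cache=True)
def _prune_kernel(
    active,
    in_cl,
    fired,
    prod_count,
    food_mask,
    dir_ent,
    ent_dir_ptr,
    ent_dir_idx,
    dir_p_ptr,
    dir_p_idx,
    cat_ptr,
    cat_idx,
    mol_dir_ptr,
    mol_dir_idx,
    mol_cat_ptr,
    mol_cat_idx,
):
    """Cascading removal of reactions violating the RAF conditions, using
    per-molecule counts of active (fired) producing directions."""
    n_ent = active.size
    n_mol = in_cl.size
    avail = in_cl.copy()
    valid = fired.copy()
    pc = prod_count.copy()
    live_dirs = np.zeros(n_ent, np.int32)
    cat_avail = np.zeros(n_ent, np.int32)
    dead = np.zeros(n_ent, np.bool_)
    for d in range(dir_ent.size):
        if valid[d]:
            live_dirs[dir_ent[d]] += 1
    ent_stack = np.empty(n_ent + 1, np.int64)
    etop = 0
    mol_stack = np.empty(n_mol + 1, np.int64)
    mtop = 0
    for r in range(n_ent):
        if not active[r]:
            continue
        c = 0
        for k in range(cat_ptr[r], cat_ptr[r + 1]):
            if avail[cat_idx[k]]:
                c += 1
        cat_avail[r] = c
        if live_dirs[r] == 0 or c == 0:
            dead[r] = True
            ent_stack[etop] = r
            etop += 1
    removed = 0
    while etop > 0 or mtop > 0:
        if etop > 0:
            etop -= 1
            r = ent_stack[etop]
            removed += 1
            for k in range(ent_dir_ptr[r], ent_dir_ptr[r + 1]):
                d = ent_dir_idx[k]
                if valid[d]:
                    valid[d] = False
                    for j in range(dir_p_ptr[d], dir_p_ptr[d + 1]):
                        p = dir_p_idx[j]
                        pc[p] -= 1
                        if pc[p] == 0 and avail[p] and not food_mask[p]:
                            avail[p] = False
                            mol_stack[mtop] = p
                            mtop += 1
        else:
            mtop -= 1
            x = mol_stack[mtop]
            for k in range(mol_dir_ptr[x], mol_dir_ptr[x + 1]):
                d = mol_dir_idx[k]
                if valid[d]:
                    valid[d] = False
                    r2 = dir_ent[d]
                    live_dirs[r2] -= 1
                    for j in range(dir_p_ptr[d], dir_p_ptr[d + 1]):
                        p = dir_p_idx[j]
                        pc[p] -= 1
                        if pc[p] == 0 and avail[p] and not food_mask[p]:
                            avail[p] = False
                            mol_stack[mtop] = p
                            mtop += 1
                    if live_dirs[r2] == 0 and not dead[r2]:
                        dead[r2] = True
                        ent_stack[etop] = r2
                        etop += 1
            for k in range(mol_cat_ptr[x], mol_cat_ptr[x + 1]):
                r2 = mol_cat_idx[k]
                if active[r2] and not dead[r2]:
                    cat_avail[r2] -= 1
                    if cat_avail[r2] == 0:
                        dead[r2] = True
                        ent_stack[etop] = r2
                        etop += 1
    new_active = np.logical_and(active, np.logical_not(dead))
    return new_active, removed


def _csr(lists, dtype=np.int32):
    ptr = np.zeros(len(lists) + 1, np.int64)
    for i, lst in enumerate(lists):
        ptr[i + 1] = ptr[i] + len(lst)
    idx = np.empty(int(ptr[-1]), dtype)
    pos = 0
    for lst in lists:
        for v in lst:
            idx[pos] = v
            pos += 1
    return ptr, idx


class ReactionNetwork:
    """CSR-indexed view of a CRS with fast closure and maxRAF routines."""

    def __init__(self, crs) -> None:
        self.crs = crs
        self.mol_ids: list[str] = sorted(crs.molecules)
        self.ent_ids: list[str] = sorted(crs.reactions)
        self.mol_index = {x: i for i, x in enumerate(self.mol_ids)}
        self.ent_index = {r: i for i, r in enumerate(self.ent_ids)}
        self.n_mol = len(self.mol_ids)
        self.n_ent = len(self.ent_ids)

        mi = self.mol_index
        dir_ent: list[int] = []
        dir_reacts: list[list[int]] = []
        dir_prods: list[list[int]] = []
        ent_dirs: list[list[int]] = [[] for _ in range(self.n_ent)]
        for ei, rid in enumerate(self.ent_ids):
            rxn = crs.reactions[rid]
            for side_r, side_p in rxn.directions:
                d = len(dir_ent)
                dir_ent.append(ei)
                dir_reacts.append(sorted({mi[x] for x in side_r}))
                dir_prods.append(sorted({mi[x] for x in side_p}))
                ent_dirs[ei].append(d)
        self.n_dir = len(dir_ent)
        self.dir_ent = np.asarray(dir_ent, np.int32)
        self.dir_r_ptr, self.dir_r_idx = _csr(dir_reacts)
        self.dir_p_ptr, self.dir_p_idx = _csr(dir_prods)
        self.ent_dir_ptr, self.ent_dir_idx = _csr(ent_dirs)

        cat_of = crs.catalysts_of
        cats = [sorted({mi[x] for x in cat_of[rid]}) for rid in self.ent_ids]
        self.cat_ptr, self.cat_idx = _csr(cats)
        self.has_catalyst = np.asarray([len(c) > 0 for c in cats], np.bool_)

        mol_dirs: list[list[int]] = [[] for _ in range(self.n_mol)]
        for d, reacts in enumerate(dir_reacts):
            for x in reacts:
                mol_dirs[x].append(d)
        self.mol_dir_ptr, self.mol_dir_idx = _csr(mol_dirs)
        mol_cats: list[list[int]] = [[] for _ in range(self.n_mol)]
        for ei, cs in enumerate(cats):
            for x in cs:
                mol_cats[x].append(ei)
        self.mol_cat_ptr, self.mol_cat_idx = _csr(mol_cats)

        self.food_idx = np.asarray(sorted(mi[x] for x in crs.food), np.int32)
        self.food_mask = np.zeros(self.n_mol, np.bool_)
        self.food_mask[self.food_idx] = True

    # -- mask/id helpers ---------------------------------------------------
    def mask_from_ids(self, rids) -> np.ndarray:
        mask = np.zeros(self.n_ent, np.bool_)
        for rid in rids:
            mask[self.ent_index[rid]] = True
        return mask

    def ids_from_mask(self, mask) -> frozenset[str]:
        return frozenset(self.ent_ids[i] for i in np.flatnonzero(mask))

    def molecule_ids_from_mask(self, mask) -> frozenset[str]:
        return frozenset(self.mol_ids[i] for i in np.flatnonzero(mask))

    def full_mask(self) -> np.ndarray:
        return np.ones(self.n_ent, np.bool_)

    # -- kernels -----------------------------------------------------------
    def closure(self, active: np.ndarray):
        """(in_cl, dir_fired, producer_counts-by-direction) for an entity mask."""
        return _closure_kernel(
            active,
            self.dir_ent,
            self.dir_r_ptr,
            self.dir_r_idx,
            self.dir_p_ptr,
            self.dir_p_idx,
            self.mol_dir_ptr,
            self.mol_dir_idx,
            self.food_idx,
            self.n_mol,
        )

    def filter_f(self, active, in_cl, dir_fired) -> np.ndarray:
        return _filter_f_kernel(
            active,
            in_cl,
            dir_fired,
            self.dir_ent,
            self.ent_dir_ptr,
            self.ent_dir_idx,
            self.cat_ptr,
            self.cat_idx,
        )

    def prune(self, active, in_cl, dir_fired, prod_count):
        return _prune_kernel(
            active,
            in_cl,
            dir_fired,
            prod_count,
            self.food_mask,
            self.dir_ent,
            self.ent_dir_ptr,
            self.ent_dir_idx,
            self.dir_p_ptr,
            self.dir_p_idx,
            self.cat_ptr,
            self.cat_idx,
            self.mol_dir_ptr,
            self.mol_dir_idx,
            self.mol_cat_ptr,
            self.mol_cat_idx,
        )

    def entity_fired(self, dir_fired) -> np.ndarray:
        out = np.zeros(self.n_ent, np.bool_)
        for d in np.flatnonzero(dir_fired):
            out[self.dir_ent[d]] = True
        return out

    def fired_products(self, ei: int, dir_fired) -> frozenset[str]:
        """Molecule ids produced by the fired directions of entity ``ei``."""
        out: set[str] = set()
        for k in range(self.ent_dir_ptr[ei], self.ent_dir_ptr[ei + 1]):
            d = self.ent_dir_idx[k]
            if dir_fired[d]:
                for j in range(self.dir_p_ptr[d], self.dir_p_ptr[d + 1]):
                    out.add(self.mol_ids[self.dir_p_idx[j]])
        return frozenset(out)

    # -- maxRAF drivers ----------------------------------------------------
    def maxraf_basic(self, active0: np.ndarray):
        """Iterate f to its first fixed point.  Returns (mask, closure_calls,
        iterations).  Reactions without any catalyst can never satisfy the RA
        condition and are discarded up front without a closure call."""
        active = np.logical_and(active0, self.has_catalyst)
        calls = 0
        iters = 0
        if not active.any():
            if active0.any():
                # one f application on the original set confirms emptiness
                self.closure(active0)
                calls = 1
                iters = 1
            return active, calls, iters
        while True:
            in_cl, fired, _ = self.closure(active)
            calls += 1
            iters += 1
            keep = self.filter_f(active, in_cl, fired)
            if np.array_equal(keep, active):
                return active, calls, iters
            if not keep.any():
                return keep, calls, iters
            active = keep

    def maxraf_modified(self, active0: np.ndarray):
        """pRAF-accelerated maxRAF: one closure per outer iteration, with
        cascading count-based pruning in between.  Returns (mask,
        closure_calls, outer_iterations)."""
        active = np.logical_and(active0, self.has_catalyst)
        calls = 0
        iters = 0
        if not active.any():
            if active0.any():
                self.closure(active0)
                calls = 1
                iters = 1
            return active, calls, iters
        while True:
            in_cl, fired, pc = self.closure(active)
            calls += 1
            iters += 1
            new_active, removed = self.prune(active, in_cl, fired, pc)
            if removed == 0:
                return active, calls, iters
            if not new_active.any():
                return new_active, calls, iters
            active = new_active

    def restricted_to(self, rids) -> "ReactionNetwork":
        """A fresh network over a reaction subset (for tight sampling loops)."""
        from .crs import CRS

        crs = self.crs
        keep = set(rids)
        mols: set[str] = set(crs.food)
        rxns = []
        for rid in sorted(keep):
            r = crs.reactions[rid]
            rxns.append(r)
            mols |= r.molecules()
        cat = [(x, r) for x, r in crs.catalysis if r in keep]
        inh = [(x, r) for x, r in crs.inhibition if r in keep]
        mols |= {x for x, _ in cat}
        mols |= {x for x, _ in inh}
        sub = CRS(
            molecules=sorted(mols),
            reactions=rxns,
            catalysis=cat,
            inhibition=inh,
            food=sorted(crs.food),
        )
        return sub.network()
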