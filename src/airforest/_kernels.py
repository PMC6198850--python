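"""Numba kernels for tree growing, prediction and permutation scoring.

Everything here operates on the encoded representation produced by
:mod:`airforest.data`: covariates as a float64 matrix in which factor
columns hold integer level codes 0..k-1, outcomes as int64 class labels
(classification) or float64 values (regression).

Shadow (pseudo) variables occupy indices ``p .. 2p-1`` of the candidate
pool.  A candidate index ``j >= p`` is resolved on the fly as column
``j - p`` read through the forest-level row reordering ``perm``, so the
data matrix is never physically doubled.

Impurity bookkeeping uses the "sum of squared class counts" identity:
for a node with class counts ``c`` and size ``n`` the node-size-weighted
Gini impurity is ``n * Gini = n - sum(c^2)/n``, hence the weighted
impurity decrease of a split is

    gain = sum(cL^2)/nL + sum(cR^2)/nR - sum(c^2)/n  >= 0.

For regression the same holds with class-count squares replaced by
squared outcome sums (``gain = sL^2/nL + sR^2/nR - s^2/n``), which equals
the reduction in total within-node sum of squares.  These quantities are
exactly the node-size-weighted decreases accumulated by the impurity
importance.
"""

import numpy as np
from numba import njit

TASK_CLS = 0
TASK_REG = 1

KIND_NUMERIC = 0  # continuous, binary/SNP and ordered factors: threshold rules
KIND_NOMINAL = 1  # unordered factors: level-subset rules

RESAMPLE_BOOTSTRAP = 0
RESAMPLE_SUBSAMPLE = 1

# noise floor for split gains; true gains involve integer count arithmetic
# (classification) or are relative to the parent score (regression)
_TOL_CLS = 1e-10


@njit(cache=True)
def _split_numeric_cls(v, labels, J):
    """Best threshold split of a numeric column, binary/multiclass Gini.

    Returns (gain, threshold); gain == 0.0 means no admissible split.
    """
    m = v.shape[0]
    order = np.argsort(v)
    right = np.zeros(J, np.float64)
    for i in range(m):
        right[labels[i]] += 1.0
    sq_parent = 0.0
    for j in range(J):
        sq_parent += right[j] * right[j]
    base = sq_parent / m
    left = np.zeros(J, np.float64)
    sq_l = 0.0
    sq_r = sq_parent
    best = 0.0
    thr = np.nan
    for i in range(m - 1):
        o = order[i]
        c = labels[o]
        sq_l += 2.0 * left[c] + 1.0
        left[c] += 1.0
        sq_r += -2.0 * right[c] + 1.0
        right[c] -= 1.0
        vi = v[o]
        vnext = v[order[i + 1]]
        if vi < vnext:
            nl = i + 1.0
            nr = m - nl
            gain = sq_l / nl + sq_r / nr - base
            if gain > best and gain > _TOL_CLS:
                best = gain
                thr = 0.5 * (vi + vnext)
    return best, thr


@njit(cache=True)
def _split_numeric_reg(v, yv):
    """Best threshold split of a numeric column under the SSE criterion."""
    m = v.shape[0]
    order = np.argsort(v)
    s_tot = 0.0
    for i in range(m):
        s_tot += yv[i]
    base = s_tot * s_tot / m
    tol = 1e-9 * (base + 1.0)
    s_l = 0.0
    best = 0.0
    thr = np.nan
    for i in range(m - 1):
        o = order[i]
        s_l += yv[o]
        vi = v[o]
        vnext = v[order[i + 1]]
        if vi < vnext:
            nl = i + 1.0
            nr = m - nl
            s_r = s_tot - s_l
            gain = s_l * s_l / nl + s_r * s_r / nr - base
            if gain > best and gain > tol:
                best = gain
                thr = 0.5 * (vi + vnext)
    return best, thr


@njit(cache=True)
def _split_nominal_cls(codes, labels, J, k, max_exh):
    """Best level-subset split of a nominal column (Gini).

    All 2-partitions of the observed levels are enumerated when their
    number is <= max_exh; beyond that, levels are ordered by class-1
    frequency and split as ordered, which is exactly optimal for binary
    outcomes.  Returns (gain, left-level bitmask).
    """
    m = codes.shape[0]
    cnt = np.zeros((k, J), np.float64)
    tot = np.zeros(k, np.float64)
    for i in range(m):
        l = np.int64(codes[i])
        cnt[l, labels[i]] += 1.0
        tot[l] += 1.0
    obs = np.empty(k, np.int64)
    k_obs = 0
    for l in range(k):
        if tot[l] > 0.0:
            obs[k_obs] = l
            k_obs += 1
    best = 0.0
    best_mask = np.int64(0)
    if k_obs < 2:
        return best, best_mask
    pc = np.zeros(J, np.float64)
    for b in range(k_obs):
        for j in range(J):
            pc[j] += cnt[obs[b], j]
    sq_parent = 0.0
    for j in range(J):
        sq_parent += pc[j] * pc[j]
    base = sq_parent / m

    if k_obs <= max_exh:
        # one side always contains the last observed level: enumerating
        # subsets of the first k_obs-1 levels covers every bipartition once
        lcnt = np.zeros(J, np.float64)
        n_mask = (np.int64(1) << np.int64(k_obs - 1)) - 1
        for mask in range(1, n_mask + 1):
            for j in range(J):
                lcnt[j] = 0.0
            nl = 0.0
            for b in range(k_obs - 1):
                if (mask >> b) & 1:
                    l = obs[b]
                    nl += tot[l]
                    for j in range(J):
                        lcnt[j] += cnt[l, j]
            nr = m - nl
            if nl == 0.0 or nr == 0.0:
                continue
            sq_l = 0.0
            sq_r = 0.0
            for j in range(J):
                sq_l += lcnt[j] * lcnt[j]
                rj = pc[j] - lcnt[j]
                sq_r += rj * rj
            gain = sq_l / nl + sq_r / nr - base
            if gain > best and gain > _TOL_CLS:
                best = gain
                gm = np.int64(0)
                for b in range(k_obs - 1):
                    if (mask >> b) & 1:
                        gm |= np.int64(1) << obs[b]
                best_mask = gm
        return best, best_mask

    # ordering shortcut (binary outcome enforced upstream)
    ratio = np.empty(k_obs, np.float64)
    for b in range(k_obs):
        l = obs[b]
        ratio[b] = cnt[l, 1] / tot[l]
    order = np.argsort(ratio)
    l0 = 0.0
    l1 = 0.0
    nl = 0.0
    run_mask = np.int64(0)
    for b in range(k_obs - 1):
        l = obs[order[b]]
        nl += tot[l]
        l0 += cnt[l, 0]
        l1 += cnt[l, 1]
        run_mask |= np.int64(1) << l
        nr = m - nl
        r0 = pc[0] - l0
        r1 = pc[1] - l1
        gain = (l0 * l0 + l1 * l1) / nl + (r0 * r0 + r1 * r1) / nr - base
        if gain > best and gain > _TOL_CLS:
            best = gain
            best_mask = run_mask
    return best, best_mask


@njit(cache=True)
def _split_nominal_reg(codes, yv, k, max_exh):
    """Best level-subset split of a nominal column under SSE."""
    m = codes.shape[0]
    s = np.zeros(k, np.float64)
    tot = np.zeros(k, np.float64)
    s_tot = 0.0
    for i in range(m):
        l = np.int64(codes[i])
        s[l] += yv[i]
        tot[l] += 1.0
        s_tot += yv[i]
    obs = np.empty(k, np.int64)
    k_obs = 0
    for l in range(k):
        if tot[l] > 0.0:
            obs[k_obs] = l
            k_obs += 1
    best = 0.0
    best_mask = np.int64(0)
    if k_obs < 2:
        return best, best_mask
    base = s_tot * s_tot / m
    tol = 1e-9 * (base + 1.0)

    if k_obs <= max_exh:
        n_mask = (np.int64(1) << np.int64(k_obs - 1)) - 1
        for mask in range(1, n_mask + 1):
            nl = 0.0
            sl = 0.0
            for b in range(k_obs - 1):
                if (mask >> b) & 1:
                    l = obs[b]
                    nl += tot[l]
                    sl += s[l]
            nr = m - nl
            if nl == 0.0 or nr == 0.0:
                continue
            sr = s_tot - sl
            gain = sl * sl / nl + sr * sr / nr - base
            if gain > best and gain > tol:
                best = gain
                gm = np.int64(0)
                for b in range(k_obs - 1):
                    if (mask >> b) & 1:
                        gm |= np.int64(1) << obs[b]
                best_mask = gm
        return best, best_mask

    # order observed levels by outcome mean, then split as ordered
    mean = np.empty(k_obs, np.float64)
    for b in range(k_obs):
        l = obs[b]
        mean[b] = s[l] / tot[l]
    order = np.argsort(mean)
    nl = 0.0
    sl = 0.0
    run_mask = np.int64(0)
    for b in range(k_obs - 1):
        l = obs[order[b]]
        nl += tot[l]
        sl += s[l]
        run_mask |= np.int64(1) << l
        nr = m - nl
        sr = s_tot - sl
        gain = sl * sl / nl + sr * sr / nr - base
        if gain > best and gain > tol:
            best = gain
            best_mask = run_mask
    return best, best_mask


@njit(cache=True)
def grow_tree(X, y_cls, y_reg, task, J, kinds, n_levels, perm,
              resample_mode, sub_k, mtry, min_node_size, pool_size, max_exh,
              seed, sv, sval, smask, lc, rc, leaf, acc, inbag_count):
    """Grow one tree; fills the preallocated node arrays in place.

    Per-tree randomness (resampling, candidate draws) is driven by
    ``seed`` alone so trees are reproducible independent of scheduling.
    Split gains are accumulated into ``acc`` indexed by the raw pool
    index, i.e. shadow splits land in acc[p:].  Returns the node count.
    """
    np.random.seed(seed)
    n = X.shape[0]
    p = X.shape[1]

    # resample
    for i in range(n):
        inbag_count[i] = 0
    if resample_mode == RESAMPLE_BOOTSTRAP:
        n_inbag = n
        idx = np.empty(n, np.int64)
        for i in range(n):
            r = np.random.randint(0, n)
            idx[i] = r
            inbag_count[r] += 1
    else:
        n_inbag = sub_k
        pick = np.arange(n)
        for i in range(sub_k):
            r = i + np.random.randint(0, n - i)
            t = pick[i]
            pick[i] = pick[r]
            pick[r] = t
        idx = pick[:sub_k].copy()
        for i in range(sub_k):
            inbag_count[idx[i]] += 1

    cap = sv.shape[0]
    st_node = np.empty(cap, np.int64)
    st_lo = np.empty(cap, np.int64)
    st_hi = np.empty(cap, np.int64)
    pool = np.arange(pool_size)
    vbuf = np.empty(n_inbag, np.float64)
    lbuf = np.empty(n_inbag, np.int64)
    ybuf = np.empty(n_inbag, np.float64)

    n_nodes = 1
    top = 0
    st_node[0] = 0
    st_lo[0] = 0
    st_hi[0] = n_inbag

    while top >= 0:
        node = st_node[top]
        lo = st_lo[top]
        hi = st_hi[top]
        top -= 1
        m = hi - lo

        is_pure = False
        if task == TASK_CLS:
            cnts = np.zeros(J, np.int64)
            for i in range(lo, hi):
                cnts[y_cls[idx[i]]] += 1
            bestc = 0
            bestn = np.int64(-1)
            nz = 0
            for j in range(J):
                if cnts[j] > 0:
                    nz += 1
                if cnts[j] > bestn:
                    bestn = cnts[j]
                    bestc = j
            leaf_val = float(bestc)
            is_pure = nz <= 1
        else:
            ssum = 0.0
            ssq = 0.0
            for i in range(lo, hi):
                yy = y_reg[idx[i]]
                ssum += yy
                ssq += yy * yy
            leaf_val = ssum / m
            is_pure = (ssq - ssum * ssum / m) <= 1e-12 * (ssq + 1.0)

        sv[node] = -1
        sval[node] = np.nan
        smask[node] = -1
        leaf[node] = leaf_val
        if is_pure or m <= min_node_size or m < 2:
            continue

        best_gain = 0.0
        best_j = -1
        best_thr = np.nan
        best_mask = np.int64(0)
        best_nominal = False
        if task == TASK_CLS:
            for i in range(m):
                lbuf[i] = y_cls[idx[lo + i]]
        else:
            for i in range(m):
                ybuf[i] = y_reg[idx[lo + i]]

        for ci in range(mtry):
            r = ci + np.random.randint(0, pool_size - ci)
            t = pool[ci]
            pool[ci] = pool[r]
            pool[r] = t
            j = pool[ci]
            col = j if j < p else j - p
            pseudo = j >= p
            for i in range(m):
                row = idx[lo + i]
                if pseudo:
                    row = perm[row]
                vbuf[i] = X[row, col]
            v = vbuf[:m]
            if kinds[col] == KIND_NOMINAL:
                if task == TASK_CLS:
                    gain, mk = _split_nominal_cls(v, lbuf[:m], J, n_levels[col], max_exh)
                else:
                    gain, mk = _split_nominal_reg(v, ybuf[:m], n_levels[col], max_exh)
                if gain > best_gain:
                    best_gain = gain
                    best_j = j
                    best_mask = mk
                    best_nominal = True
            else:
                if task == TASK_CLS:
                    gain, thr = _split_numeric_cls(v, lbuf[:m], J)
                else:
                    gain, thr = _split_numeric_reg(v, ybuf[:m])
                if gain > best_gain:
                    best_gain = gain
                    best_j = j
                    best_thr = thr
                    best_nominal = False

        if best_j < 0:
            continue

        col = best_j if best_j < p else best_j - p
        pseudo = best_j >= p
        iL = lo
        iR = hi - 1
        while iL <= iR:
            row = idx[iL]
            rrow = perm[row] if pseudo else row
            val = X[rrow, col]
            if best_nominal:
                go_left = ((best_mask >> np.int64(val)) & 1) == 1
            else:
                go_left = val <= best_thr
            if go_left:
                iL += 1
            else:
                idx[iL] = idx[iR]
                idx[iR] = row
                iR -= 1
        n_left = iL - lo
        if n_left == 0 or n_left == m:
            continue  # numerically degenerate; keep as leaf

        acc[best_j] += best_gain
        sv[node] = best_j
        if best_nominal:
            smask[node] = best_mask
            sval[node] = np.nan
        else:
            sval[node] = best_thr
            smask[node] = -1
        li = n_nodes
        ri = n_nodes + 1
        n_nodes += 2
        lc[node] = li
        rc[node] = ri
        top += 1
        st_node[top] = li
        st_lo[top] = lo
        st_hi[top] = iL
        top += 1
        st_node[top] = ri
        st_lo[top] = iL
        st_hi[top] = hi

    return n_nodes


@njit(cache=True)
def predict_rows(X, perm, p, sv, sval, smask, lc, rc, leaf, rows, out,
                 override_var, override_vals):
    """Drop rows of X through one tree; leaf payloads land in ``out``.

    ``override_var >= 0`` substitutes ``override_vals[i]`` for the value
    of that variable when routing ``rows[i]`` (used by the permutation
    importance).  Shadow splits (var >= p) read through ``perm``.
    """
    for ii in range(rows.shape[0]):
        row = rows[ii]
        node = 0
        while sv[node] >= 0:
            j = sv[node]
            if j == override_var:
                val = override_vals[ii]
            elif j < p:
                val = X[row, j]
            else:
                val = X[perm[row], j - p]
            if smask[node] >= 0:
                go_left = ((smask[node] >> np.int64(val)) & 1) == 1
            else:
                go_left = val <= sval[node]
            node = lc[node] if go_left else rc[node]
        out[ii] = leaf[node]


@njit(cache=True)
def _eval_error(preds, rows, y_cls, y_reg, task):
    n = rows.shape[0]
    err = 0.0
    if task == TASK_CLS:
        for ii in range(n):
            if np.int64(preds[ii]) != y_cls[rows[ii]]:
                err += 1.0
    else:
        for ii in range(n):
            d = preds[ii] - y_reg[rows[ii]]
            err += d * d
    return err / n


@njit(cache=True)
def tree_permutation_scores(X, y_cls, y_reg, task, perm, p,
                            sv, sval, smask, lc, rc, leaf,
                            rows, seed, scores):
    """Accumulate one tree's permutation-importance contributions.

    ``rows`` is the evaluation set (the tree's OOB rows, or a held-out
    half).  For each variable used by the tree, a fresh permutation of
    its values over ``rows`` is drawn, the error increase relative to
    the unpermuted error is added to ``scores``.  Unused variables are
    untouched, so they contribute exactly zero.  Returns the baseline
    error, or -1.0 when the evaluation set is too small.
    """
    n_rows = rows.shape[0]
    if n_rows < 2:
        return -1.0
    np.random.seed(seed)
    preds = np.empty(n_rows, np.float64)
    empty = np.empty(0, np.float64)
    predict_rows(X, perm, p, sv, sval, smask, lc, rc, leaf, rows, preds, -1, empty)
    err0 = _eval_error(preds, rows, y_cls, y_reg, task)

    used = np.zeros(p, np.bool_)
    for node in range(sv.shape[0]):
        if 0 <= sv[node] < p:
            used[sv[node]] = True

    vals = np.empty(n_rows, np.float64)
    for v in range(p):
        if not used[v]:
            continue
        for ii in range(n_rows):
            vals[ii] = X[rows[ii], v]
        for ii in range(n_rows - 1, 0, -1):
            r = np.random.randint(0, ii + 1)
            t = vals[ii]
            vals[ii] = vals[r]
            vals[r] = t
        predict_rows(X, perm, p, sv, sval, smask, lc, rc, leaf, rows, preds, v, vals)
        err = _eval_error(preds, rows, y_cls, y_reg, task)
        scores[v] += err - err0
    return err0
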