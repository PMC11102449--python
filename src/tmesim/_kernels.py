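"""Compiled per-agent update rules.

Everything here operates on the flat arrays held by
:class:`tmesim.core_types.Lattice` plus the oxygen grid, so the same rule
code backs both the single-rule operations in :mod:`tmesim.agents_dynamics`
and the fused shuffled agent phase used by the engine.  All randomness
flows through a single ``numpy.random.Generator`` passed in explicitly.
"""

import numpy as np
from numba import njit

# agent kind codes (must match tmesim.core_types.AgentKind)
EMPTY = 0
TUMOR = 1
DC_INACTIVE = 2
DC_ACTIVE = 3
T_INACTIVE = 4
TREG = 5
EFFECTOR = 6

# Moore offsets; index 7-d is the opposite of direction d.
DR8 = np.array([-1, -1, -1, 0, 0, 1, 1, 1], dtype=np.int64)
DC8 = np.array([-1, 0, 1, -1, 1, -1, 0, 1], dtype=np.int64)

# kernel-parameter vector layout (see ParameterSet.kernel_array)
K_PTUMOR = 0
K_RHT = 1
K_RAT = 2
K_C = 3
K_PTREG = 4
K_RHR = 5
K_RAR = 6
K_MU = 7
K_RHE = 8
K_RAE = 9
K_DACT = 10
K_CACT = 11
K_DINACT = 12
K_LEXP = 13
K_HREF = 14
K_ADREF = 15
N_KERNEL_PARAMS = 16


@njit(cache=True)
def dir_index(dr, dc):
    q = (dr + 1) * 3 + (dc + 1)
    return q - 1 if q > 4 else q


@njit(cache=True)
def levy_run_length(u, l_exp):
    """Inverse-CDF draw of the power-law run length z = ceil((1-u)^(-1/l))."""
    return np.int64(np.ceil((1.0 - u) ** (-1.0 / l_exp)))


@njit(cache=True)
def clamp01(x):
    if x < 0.0:
        return 0.0
    if x > 1.0:
        return 1.0
    return x


@njit(cache=True)
def tumor_rate_kernel(u_local, ad, pk):
    h = 1.0 / (u_local + pk[K_C]) - pk[K_HREF]
    return clamp01(pk[K_PTUMOR] + pk[K_RHT] * h + pk[K_RAT] * (ad - pk[K_ADREF]))


@njit(cache=True)
def treg_rate_kernel(u_local, ad, pk):
    return clamp01(pk[K_PTREG] + pk[K_RHR] / (u_local + pk[K_C]) + pk[K_RAR] * ad)


@njit(cache=True)
def cytotoxicity_rate_kernel(u_local, ad, pk):
    return clamp01(pk[K_MU] - pk[K_RHE] / (u_local + pk[K_C]) - pk[K_RAE] * ad)


@njit(cache=True)
def levy_move(grid, kind, row, col, direction, steps, i, l_exp, rng):
    """One Levy-walk step: draw a fresh run if exhausted, then try to move.

    A fresh direction is drawn uniformly among currently empty in-grid
    neighbors (deferred to the next step if there are none) and the cell
    moves immediately on the draw step.  A blocked move is forfeited but
    still consumes one step of the run; an out-of-grid target mirrors the
    offending direction component(s) for subsequent steps.
    """
    n = grid.shape[0]
    r = row[i]
    c = col[i]
    if steps[i] == 0:
        cnt = 0
        cand = np.empty(8, np.int64)
        for d in range(8):
            nr = r + DR8[d]
            nc = c + DC8[d]
            if 0 <= nr < n and 0 <= nc < n and grid[nr, nc] == EMPTY:
                cand[cnt] = d
                cnt += 1
        if cnt == 0:
            return
        direction[i] = cand[rng.integers(0, cnt)]
        steps[i] = levy_run_length(rng.random(), l_exp)
    d = direction[i]
    nr = r + DR8[d]
    nc = c + DC8[d]
    if nr < 0 or nr >= n or nc < 0 or nc >= n:
        ndr = DR8[d]
        ndc = DC8[d]
        if nr < 0 or nr >= n:
            ndr = -ndr
        if nc < 0 or nc >= n:
            ndc = -ndc
        direction[i] = dir_index(ndr, ndc)
    elif grid[nr, nc] == EMPTY:
        grid[r, c] = EMPTY
        grid[nr, nc] = kind[i]
        row[i] = nr
        col[i] = nc
    steps[i] -= 1
    if steps[i] < 0:
        steps[i] = 0


@njit(cache=True)
def brownian_move(grid, kind, row, col, i, rng):
    """One Brownian step: uniform among all 8 directions, move if legal."""
    n = grid.shape[0]
    r = row[i]
    c = col[i]
    d = rng.integers(0, 8)
    nr = r + DR8[d]
    nc = c + DC8[d]
    if 0 <= nr < n and 0 <= nc < n and grid[nr, nc] == EMPTY:
        grid[r, c] = EMPTY
        grid[nr, nc] = kind[i]
        row[i] = nr
        col[i] = nc


@njit(cache=True)
def try_divide(grid, tumor_row, tumor_col, tumor_slot, blk_tumor, n_tumor,
               slot, U, ad, pk, rng):
    """Rim-only division of the tumor cell in ``slot``; returns new n_tumor.

    Division happens with probability p̄_tumor(U at the mother's site, Ad)
    and requires at least one empty Moore neighbor; the daughter occupies a
    uniformly chosen empty neighbor.
    """
    n = grid.shape[0]
    r = tumor_row[slot]
    c = tumor_col[slot]
    cnt = 0
    cand = np.empty(8, np.int64)
    for d in range(8):
        nr = r + DR8[d]
        nc = c + DC8[d]
        if 0 <= nr < n and 0 <= nc < n and grid[nr, nc] == EMPTY:
            cand[cnt] = d
            cnt += 1
    if cnt == 0:
        return n_tumor
    p = tumor_rate_kernel(U[r, c], ad, pk)
    if rng.random() >= p:
        return n_tumor
    d = cand[rng.integers(0, cnt)]
    nr = r + DR8[d]
    nc = c + DC8[d]
    grid[nr, nc] = TUMOR
    tumor_row[n_tumor] = nr
    tumor_col[n_tumor] = nc
    tumor_slot[nr, nc] = n_tumor
    blk_tumor[nr // 3, nc // 3] += 1
    return n_tumor + 1


@njit(cache=True)
def try_dc_activation(grid, kind, steps, row, col, i, pk, rng):
    """Inactive DC adjacent to >=1 tumor site activates at rate D_act."""
    n = grid.shape[0]
    r = row[i]
    c = col[i]
    for d in range(8):
        nr = r + DR8[d]
        nc = c + DC8[d]
        if 0 <= nr < n and 0 <= nc < n and grid[nr, nc] == TUMOR:
            if rng.random() < pk[K_DACT]:
                kind[i] = DC_ACTIVE
                grid[r, c] = DC_ACTIVE
                steps[i] = 0
            return True
    return False


@njit(cache=True)
def try_dc_inactivation(grid, kind, steps, row, col, i, pk, rng):
    """Active DC adjacent to >=1 Treg deactivates at rate D_inact."""
    n = grid.shape[0]
    r = row[i]
    c = col[i]
    for d in range(8):
        nr = r + DR8[d]
        nc = c + DC8[d]
        if 0 <= nr < n and 0 <= nc < n and grid[nr, nc] == TREG:
            if rng.random() < pk[K_DINACT]:
                kind[i] = DC_INACTIVE
                grid[r, c] = DC_INACTIVE
                steps[i] = 0  # fresh Levy run
            return True
    return False


@njit(cache=True)
def try_t_activation(grid, kind, steps, row, col, i, U, ad, pk, rng):
    """Inactive T cell next to an active DC activates at rate C_act.

    On activation one adjacent active DC is chosen uniformly as the
    activator; the cell becomes a Treg with probability p̄_Treg evaluated at
    the activator's site, otherwise an effector.
    """
    n = grid.shape[0]
    r = row[i]
    c = col[i]
    cnt = 0
    cand = np.empty(8, np.int64)
    for d in range(8):
        nr = r + DR8[d]
        nc = c + DC8[d]
        if 0 <= nr < n and 0 <= nc < n and grid[nr, nc] == DC_ACTIVE:
            cand[cnt] = d
            cnt += 1
    if cnt == 0:
        return False
    if rng.random() < pk[K_CACT]:
        d = cand[rng.integers(0, cnt)]
        ur = r + DR8[d]
        uc = c + DC8[d]
        p_treg = treg_rate_kernel(U[ur, uc], ad, pk)
        if rng.random() < p_treg:
            kind[i] = TREG
            grid[r, c] = TREG
        else:
            kind[i] = EFFECTOR
            grid[r, c] = EFFECTOR
        steps[i] = 0
    return True


@njit(cache=True)
def try_kill(grid, tumor_row, tumor_col, tumor_slot, blk_tumor, r, c,
             U, ad, pk, rng):
    """Serial-killing attempt by the effector at (r, c); returns 1 on a kill.

    One adjacent tumor cell is chosen uniformly and removed with probability
    µ̄(U at the effector's site, Ad); the vacated site becomes empty and the
    effector survives.  The tumor slot is tombstoned (row = -1) and cleaned
    up by :func:`compact_tumor` after the phase.
    """
    n = grid.shape[0]
    cnt = 0
    cand = np.empty(8, np.int64)
    for d in range(8):
        nr = r + DR8[d]
        nc = c + DC8[d]
        if 0 <= nr < n and 0 <= nc < n and grid[nr, nc] == TUMOR:
            cand[cnt] = d
            cnt += 1
    if cnt == 0:
        return 0
    p = cytotoxicity_rate_kernel(U[r, c], ad, pk)
    if rng.random() >= p:
        return 0
    d = cand[rng.integers(0, cnt)]
    nr = r + DR8[d]
    nc = c + DC8[d]
    slot = tumor_slot[nr, nc]
    tumor_row[slot] = -1
    tumor_slot[nr, nc] = -1
    grid[nr, nc] = EMPTY
    blk_tumor[nr // 3, nc // 3] -= 1
    return 1


@njit(cache=True)
def compact_tumor(tumor_row, tumor_col, tumor_slot, n_tumor):
    """Remove tombstoned tumor slots in place; returns the live count."""
    w = 0
    for j in range(n_tumor):
        if tumor_row[j] >= 0:
            if w != j:
                tumor_row[w] = tumor_row[j]
                tumor_col[w] = tumor_col[j]
                tumor_slot[tumor_row[w], tumor_col[w]] = w
            w += 1
    return w


@njit(cache=True)
def block_residual_means(U, u_boundary):
    """Per-block means of U - u_boundary over the fixed 3x3 partition."""
    nb = U.shape[0] // 3
    S = np.empty((nb, nb), dtype=np.float64)
    for bi in range(nb):
        for bj in range(nb):
            acc = 0.0
            for i in range(3 * bi, 3 * bi + 3):
                for j in range(3 * bj, 3 * bj + 3):
                    acc += U[i, j] - u_boundary
            S[bi, bj] = acc / 9.0
    return S


@njit(cache=True)
def coarse_diffusion(S, sink, alpha, bw, substeps, u_boundary):
    """In-place relaxation sub-iterations of the block diffusion scheme.

    Each sub-iteration: 3x3 Moore smoothing (replicate-padded) at rate
    ``alpha``, minus the per-sub-iteration sink, clamped so reconstructed
    fine values stay >= 0, then scaled by the boundary-pinning weight.
    """
    nb = S.shape[0]
    R = np.empty_like(S)
    A = np.empty_like(S)
    for _ in range(substeps):
        for i in range(nb):
            im = i - 1 if i > 0 else 0
            ip = i + 1 if i < nb - 1 else nb - 1
            for j in range(nb):
                R[i, j] = S[im, j] + S[i, j] + S[ip, j]
        for i in range(nb):
            for j in range(nb):
                jm = j - 1 if j > 0 else 0
                jp = j + 1 if j < nb - 1 else nb - 1
                A[i, j] = (R[i, jm] + R[i, j] + R[i, jp]) / 9.0
        for i in range(nb):
            for j in range(nb):
                v = S[i, j] + alpha * (A[i, j] - S[i, j]) - sink[i, j]
                if v < -u_boundary:
                    v = -u_boundary
                S[i, j] = v * bw[i, j]
    return S


@njit(cache=True)
def reconstruct_fine(U, S, u_boundary):
    """Write the fine grid from block values: redistribute, clamp, pin."""
    n = U.shape[0]
    nb = n // 3
    for bi in range(nb):
        for bj in range(nb):
            v = u_boundary + S[bi, bj]
            if v < 0.0:
                v = 0.0
            for i in range(3 * bi, 3 * bi + 3):
                for j in range(3 * bj, 3 * bj + 3):
                    U[i, j] = v
    for i in range(n):
        U[0, i] = u_boundary
        U[n - 1, i] = u_boundary
        U[i, 0] = u_boundary
        U[i, n - 1] = u_boundary


@njit(cache=True)
def find_rim_slots(grid, tumor_row, tumor_col, n_tumor, out):
    """Slots of tumor cells with >=1 empty Moore neighbor; returns count."""
    n = grid.shape[0]
    cnt = 0
    for j in range(n_tumor):
        r = tumor_row[j]
        c = tumor_col[j]
        for d in range(8):
            nr = r + DR8[d]
            nc = c + DC8[d]
            if 0 <= nr < n and 0 <= nc < n and grid[nr, nc] == EMPTY:
                out[cnt] = j
                cnt += 1
                break
    return cnt


@njit(cache=True)
def agent_phase(grid, kind, row, col, direction, steps,
                tumor_row, tumor_col, tumor_slot, blk_tumor, n_tumor,
                rim_slots, U, ad, pk, perm, rng):
    """One shuffled agent phase over all immune agents and rim tumor cells.

    ``perm`` is a permutation of ``n_immune + n_rim`` indices; entries
    below ``n_immune`` address immune agents (interaction rule, then
    movement), the rest index into ``rim_slots`` (division attempts; only
    cells on the tumor rim at the start of the step can divide).  Daughters
    born during the phase do not act until the next step; tumor cells killed
    earlier in the phase no longer act.  Returns (n_tumor, births, kills).
    """
    n_immune = kind.size
    n_tumor0 = n_tumor
    kills = 0
    l_exp = pk[K_LEXP]
    for t in range(perm.size):
        p = perm[t]
        if p < n_immune:
            i = p
            ki = kind[i]
            if ki == DC_INACTIVE:
                try_dc_activation(grid, kind, steps, row, col, i, pk, rng)
            elif ki == DC_ACTIVE:
                try_dc_inactivation(grid, kind, steps, row, col, i, pk, rng)
            elif ki == T_INACTIVE:
                try_t_activation(grid, kind, steps, row, col, i, U, ad, pk, rng)
            elif ki == EFFECTOR:
                kills += try_kill(grid, tumor_row, tumor_col, tumor_slot,
                                  blk_tumor, row[i], col[i], U, ad, pk, rng)
            ki = kind[i]  # may have changed this step
            if ki == DC_INACTIVE or ki == T_INACTIVE:
                levy_move(grid, kind, row, col, direction, steps, i, l_exp, rng)
            else:
                brownian_move(grid, kind, row, col, i, rng)
        else:
            slot = rim_slots[p - n_immune]
            if tumor_row[slot] >= 0:
                n_tumor = try_divide(grid, tumor_row, tumor_col, tumor_slot,
                                     blk_tumor, n_tumor, slot, U, ad, pk, rng)
    births = n_tumor - n_tumor0
    n_tumor = compact_tumor(tumor_row, tumor_col, tumor_slot, n_tumor)
    return n_tumor, births, kills
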