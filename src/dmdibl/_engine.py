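"""Vectorized lockstep runner for batches of Stroop sessions.

Runs n sessions simultaneously with numpy array state. Produces results
equivalent to the per-object path in ``stroop_task`` (same seeds, same RNG
consumption order: one uniform per instance per retrieval attempt), which a
test verifies. The grid search calls this path; ``prepare_sessions`` lets
it reuse sheet sequences and noise tables across parameter points, giving
common random numbers over the whole grid.
"""

from __future__ import annotations

import numpy as np

from .iblt_core import _U_EPS, ModelParams

__all__ = ["prepare_sessions", "run_sessions"]


def prepare_sessions(config, seed, n):
    """Pre-draw everything stochastic for ``n`` sessions: the three sheet
    item sequences per session and the uniform noise table (one row of
    ``2k`` uniforms per potential retrieval attempt)."""
    from .stroop_task import SHEET_KINDS, _session_rngs, make_sheet

    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    children = ss.spawn(n)
    colors = config.colors
    k = len(colors)
    n_inst = 2 * k
    N = config.n_items
    cmap = {c: i for i, c in enumerate(colors)}

    word_w = np.empty((n, N), dtype=np.int64)   # word index on word sheet
    color_i = np.empty((n, N), dtype=np.int64)  # ink index on color sheet
    cw_w = np.empty((n, N), dtype=np.int64)     # word index on color-word sheet
    cw_i = np.empty((n, N), dtype=np.int64)     # ink index on color-word sheet
    U = np.empty((n, 3 * N, n_inst))
    for s, child in enumerate(children):
        rng_sheet, rng_ret = _session_rngs(child)
        sheets = {kind: make_sheet(kind, N, colors, rng_sheet,
                                   time_budget=config.time_budget)
                  for kind in SHEET_KINDS}
        word_w[s] = [cmap[it.word] for it in sheets["word"].items]
        color_i[s] = [cmap[it.ink] for it in sheets["color"].items]
        cw_w[s] = [cmap[it.word] for it in sheets["color_word"].items]
        cw_i[s] = [cmap[it.ink] for it in sheets["color_word"].items]
        U[s] = rng_ret.random((3 * N, n_inst))
    return {
        "n": n, "k": k, "n_inst": n_inst, "N": N,
        "word_w": word_w, "color_i": color_i, "cw_w": cw_w, "cw_i": cw_i,
        "U": U,
    }


def _penalties(kind, j, prep, P):
    """Per-session penalty vector over instances for item j of a sheet.

    Instance layout mirrors ``prime_store``: indices ``0..k-1`` are the
    word-reading instances (word = color c_i, neutral ink) and ``k..2k-1``
    the color-naming instances (neutral word, ink = color c_{i-k}).
    """
    S, k, I = prep["n"], prep["k"], prep["n_inst"]
    pen = np.full((S, I), 0.0)
    rows = np.arange(S)
    if kind == "word":
        # probe requests the word slot only; only the matching word instance
        # escapes the penalty (color instances carry the neutral word).
        pen[:] = -P
        pen[rows, prep["word_w"][:, j]] = 0.0
    elif kind == "color":
        pen[:] = -P
        pen[rows, k + prep["color_i"][:, j]] = 0.0
    else:
        # both slots requested: every candidate mismatches at least one.
        pen[:] = -2.0 * P
        pen[rows, prep["cw_w"][:, j]] = -P          # word matches, ink does not
        pen[rows, k + prep["cw_i"][:, j]] = -P      # ink matches, word does not
    return pen


def run_sessions(params: ModelParams, config, prep, noise_on=True):
    """Run all prepared sessions under ``params`` and return SessionResults."""
    from .stroop_task import SHEET_KINDS, SessionResult, SheetResult, score_session

    S, I, N = prep["n"], prep["n_inst"], prep["N"]
    U = prep["U"]
    F, f, d, s_noise = params.F, params.f, params.d, params.s
    P, tau, tnr = params.P, params.tau, params.t_nonretrieval
    budget = config.time_budget
    penalty_time = config.failure_penalty

    E = 3 * N
    onehot = np.zeros((S, E, I))
    n_ev = np.zeros(S, dtype=np.int64)   # committed events per session
    ptr = np.zeros(S, dtype=np.int64)    # retrieval attempts per session
    ev_times = np.arange(1, E + 1, dtype=np.float64)
    rows = np.arange(S)

    lat = {}
    counts = {}
    fails = {}
    for kind in SHEET_KINDS:
        lat_k = np.zeros((S, N))
        cnt = np.zeros(S, dtype=np.int64)
        nfail = np.zeros(S, dtype=np.int64)
        cum = np.zeros(S)
        active = np.ones(S, dtype=bool)
        for j in range(N):
            if not active.any():
                break
            now = (n_ev + 1).astype(np.float64)
            m = int(n_ev.max())
            base = (now ** (-d))[:, None] * np.ones((1, I))  # priming at t=0
            if m > 0:
                lags = now[:, None] - ev_times[None, :m]
                valid = lags >= 1.0
                w = np.where(valid, lags, 1.0) ** (-d)
                w[~valid] = 0.0
                base += np.einsum("se,sei->si", w, onehot[:, :m, :])
            A = np.log(base) + _penalties(kind, j, prep, P)
            if noise_on:
                u = np.clip(U[rows, np.minimum(ptr, 3 * N - 1), :],
                            _U_EPS, 1.0 - _U_EPS)
                A = A + s_noise * np.log((1.0 - u) / u)
            win = np.argmax(A, axis=1)  # first max wins: lowest index on ties
            a_win = A[rows, win]
            failed = np.zeros(S, dtype=bool) if tau is None else (a_win < tau)
            rt = F * np.exp(-f * a_win) + tnr
            cost = np.where(failed, penalty_time, rt)
            fits = cum + cost <= budget

            commit = active & fits & ~failed
            failfit = active & fits & failed
            idx = np.flatnonzero(commit)
            onehot[idx, n_ev[idx], win[idx]] = 1.0
            lat_k[idx, cnt[idx]] = rt[idx]
            cnt[idx] += 1
            n_ev[idx] += 1
            nfail[failfit] += 1
            cum[commit | failfit] += cost[commit | failfit]
            ptr[active] += 1
            active &= fits
        lat[kind] = lat_k
        counts[kind] = cnt
        fails[kind] = nfail

    out = []
    for s in range(S):
        sheets = {
            kind: SheetResult(kind=kind,
                              items_completed=int(counts[kind][s]),
                              latencies=lat[kind][s, : counts[kind][s]].copy(),
                              n_failures=int(fails[kind][s]))
            for kind in SHEET_KINDS
        }
        res = score_session(sheets["word"].items_completed,
                            sheets["color"].items_completed,
                            sheets["color_word"].items_completed)
        res.sheets = sheets
        out.append(res)
    return out
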