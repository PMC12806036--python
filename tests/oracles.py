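"""Independent, loop-naive reference implementations used as test oracles.

Everything here is deliberately written in the most direct style possible
(python sets, explicit double loops, dense incidence matrices) and shares
no code with the package implementation it checks.
"""

from __future__ import annotations

import numpy as np


# -- multi-label metrics (set arithmetic) -----------------------------------


def naive_metrics(y_true: np.ndarray, y_pred: np.ndarray) -> dict[str, float]:
    n, m = y_true.shape
    precision = coverage = accuracy = abs_true = abs_false = 0.0
    for i in range(n):
        t = {j for j in range(m) if y_true[i, j] == 1}
        p = {j for j in range(m) if y_pred[i, j] == 1}
        inter = t & p
        union = t | p
        precision += len(inter) / len(p) if p else 0.0
        coverage += len(inter) / len(t)
        accuracy += len(inter) / len(union)
        abs_true += 1.0 if t == p else 0.0
        abs_false += (len(union) - len(inter)) / m
    return {
        "precision": precision / n,
        "coverage": coverage / n,
        "accuracy": accuracy / n,
        "absolute_true": abs_true / n,
        "absolute_false": abs_false / n,
    }


# -- Chou-Fasman (independent rule evaluator) --------------------------------


def naive_chou_fasman(sequence: str, table: dict[str, dict[str, float]]) -> list[int]:
    n = len(sequence)
    ph = [table[a]["p_helix"] for a in sequence]
    ps = [table[a]["p_sheet"] for a in sequence]
    pt = [table[a]["p_turn"] for a in sequence]

    def grow(p: list[float], window: int, min_hits: int) -> set[int]:
        member: set[int] = set()
        for i in range(n - window + 1):
            if sum(1 for j in range(i, i + window) if p[j] > 100.0) >= min_hits:
                member |= set(range(i, i + window))
        # maximal runs of the nucleation set, identified before any extension
        runs = []
        for start in sorted(member):
            if start - 1 in member:
                continue
            stop = start
            while stop + 1 in member:
                stop += 1
            runs.append((start, stop))
        # extend each nucleated run outward on 4-residue means
        result = set(member)
        for start, stop in runs:
            j = stop + 1
            while j < n and sum(p[j - 3 : j + 1]) / 4.0 >= 100.0:
                result.add(j)
                j += 1
            j = start - 1
            while j >= 0 and sum(p[j : j + 4]) / 4.0 >= 100.0:
                result.add(j)
                j -= 1
        return result

    helix = grow(ph, 6, 4)
    sheet = grow(ps, 5, 3)

    out = [3] * n
    for i in range(n):
        if i in helix and i not in sheet:
            out[i] = 0
        elif i in sheet and i not in helix:
            out[i] = 1
    both = helix & sheet
    for i in sorted(both):
        if i - 1 in both:
            continue
        stop = i
        while stop + 1 in both:
            stop += 1
        region = list(range(i, stop + 1))
        mh = sum(ph[j] for j in region) / len(region)
        ms = sum(ps[j] for j in region) / len(region)
        for j in region:
            out[j] = 0 if mh >= ms else 1
    for i in range(n - 3):
        prod = (
            table[sequence[i]]["f_i"]
            * table[sequence[i + 1]]["f_i1"]
            * table[sequence[i + 2]]["f_i2"]
            * table[sequence[i + 3]]["f_i3"]
        )
        mpt = sum(pt[i : i + 4]) / 4.0
        mph = sum(ph[i : i + 4]) / 4.0
        mps = sum(ps[i : i + 4]) / 4.0
        if prod > 7.5e-5 and mpt > 100.0 and mpt > mph and mpt > mps:
            for j in range(i, i + 4):
                out[j] = 2
    return out


# -- HyperGAT (dense double-loop evaluation of the update equations) ---------


def _leaky(x: float, slope: float) -> float:
    return x if x > 0 else slope * x


def _elu(x: np.ndarray) -> np.ndarray:
    return np.where(x > 0, x, np.exp(np.minimum(x, 0.0)) - 1.0)


def naive_edge_update(H, W, h_v, h_e_prev, wp_v, wp_e, slope):
    """H: dense |E|x|V| 0/1; W: per-(edge,node) weights; returns (h_e', beta)."""
    n_e, n_v = H.shape
    d = wp_v.shape[1]
    pv = h_v @ wp_v
    pe = h_e_prev @ wp_e
    h_out = np.zeros((n_e, d))
    beta = np.zeros((n_e, n_v))
    for e in range(n_e):
        members = [v for v in range(n_v) if H[e, v]]
        scores = [
            _leaky(float(np.dot(pv[v], pe[e])), slope) * W[e, v] for v in members
        ]
        mx = max(scores)
        exps = [np.exp(s - mx) for s in scores]
        z = sum(exps)
        for v, ex in zip(members, exps):
            beta[e, v] = ex / z
        acc = np.zeros(d)
        for v in members:
            acc += beta[e, v] * pv[v]
        h_out[e] = _elu(acc)
    return h_out, beta


def naive_node_update(H, h_e, h_v, w_v, w_e, slope):
    n_e, n_v = H.shape
    d = w_e.shape[1]
    tv = h_v @ w_v
    te = h_e @ w_e
    h_out = np.zeros((n_v, d))
    alpha = np.zeros((n_e, n_v))
    for v in range(n_v):
        edges = [e for e in range(n_e) if H[e, v]]
        scores = [_leaky(float(np.dot(tv[v], te[e])), slope) for e in edges]
        mx = max(scores)
        exps = [np.exp(s - mx) for s in scores]
        z = sum(exps)
        for e, ex in zip(edges, exps):
            alpha[e, v] = ex / z
        acc = np.zeros(d)
        for e in edges:
            acc += alpha[e, v] * te[e]
        h_out[v] = _elu(acc)
    return h_out, alpha


def naive_hypergat_forward(H, W, node_init, layers, readout, proj_w, proj_b, slope):
    """layers/readout: dicts with keys w_v, w_e, wp_v, wp_e (in x out arrays)."""
    h_v = node_init
    h_e = None
    for lay in layers:
        if h_e is None:
            h_e = np.stack([
                h_v[[v for v in range(H.shape[1]) if H[e, v]]].mean(axis=0)
                for e in range(H.shape[0])
            ])
        h_e, _ = naive_edge_update(H, W, h_v, h_e, lay["wp_v"], lay["wp_e"], slope)
        h_v, _ = naive_node_update(H, h_e, h_v, lay["w_v"], lay["w_e"], slope)
    boot = np.stack([
        h_v[[v for v in range(H.shape[1]) if H[e, v]]].mean(axis=0)
        for e in range(H.shape[0])
    ])
    h_e, _ = naive_edge_update(H, W, h_v, boot, readout["wp_v"], readout["wp_e"], slope)
    return h_e @ proj_w + proj_b
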