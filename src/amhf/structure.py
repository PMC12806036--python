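"""Chou-Fasman secondary-structure assignment.

The classic propensity-table heuristic: each residue carries empirical
propensities for helix, sheet and turn (values > 100 favor the state), plus
positional turn frequencies f(i)..f(i+3).  Regions are found by nucleation
(a short window dense in high-propensity residues) and extended outward
until the propensity of the trailing tetrapeptide falls below 100.  The
four output states are encoded 0 = alpha-helix, 1 = beta-sheet,
2 = beta-turn, 3 = random coil.

The propensity table ships as ``data/chou_fasman.tsv`` so it is auditable;
the parameters (nucleation windows 6/5, thresholds 100 and 7.5e-5) are the
standard published ones.

Rules, precisely:

1. helix nucleation: any 6-residue window with >= 4 residues of
   P(helix) > 100; nucleated runs extend in both directions while the mean
   P(helix) of the 4-residue window at the moving end stays >= 100;
2. sheet nucleation: any 5-residue window with >= 3 residues of
   P(sheet) > 100, extended the same way on P(sheet);
3. a turn is assigned to the tetrapeptide starting at i when
   f(i)f(i+1)f(i+2)f(i+3) > 7.5e-5, the mean P(turn) over the window
   exceeds 100, and exceeds both the mean P(helix) and mean P(sheet) there;
4. helix/sheet overlaps are resolved per maximal overlap region by the
   higher mean propensity (ties go to helix); turns are assigned last and
   override;
5. everything unassigned is coil.
"""

from __future__ import annotations

from importlib import resources

import numpy as np

from .io import validate_sequence

__all__ = ["HELIX", "SHEET", "TURN", "COIL", "PROPENSITY_TABLE", "chou_fasman"]

HELIX, SHEET, TURN, COIL = 0, 1, 2, 3

TURN_PRODUCT_THRESHOLD = 7.5e-5
PROPENSITY_THRESHOLD = 100.0


def _load_table() -> dict[str, dict[str, float]]:
    table: dict[str, dict[str, float]] = {}
    text = resources.files("amhf.data").joinpath("chou_fasman.tsv").read_text()
    lines = [ln for ln in text.strip().splitlines()]
    header = lines[0].split("\t")
    for ln in lines[1:]:
        parts = ln.split("\t")
        table[parts[0]] = {h: float(v) for h, v in zip(header[1:], parts[1:])}
    return table


#: residue -> {p_helix, p_sheet, p_turn, f_i, f_i1, f_i2, f_i3}
PROPENSITY_TABLE = _load_table()


def _runs(flag: np.ndarray):
    """Maximal runs of True as (start, stop) with stop exclusive."""
    runs = []
    i = 0
    n = len(flag)
    while i < n:
        if flag[i]:
            j = i
            while j < n and flag[j]:
                j += 1
            runs.append((i, j))
            i = j
        else:
            i += 1
    return runs


def _nucleate_extend(p: np.ndarray, window: int, min_hits: int) -> np.ndarray:
    n = len(p)
    flag = np.zeros(n, dtype=bool)
    if n < window:
        return flag
    hits = p > PROPENSITY_THRESHOLD
    for i in range(n - window + 1):
        if hits[i : i + window].sum() >= min_hits:
            flag[i : i + window] = True
    for start, stop in _runs(flag.copy()):
        j = stop
        while j < n and p[j - 3 : j + 1].mean() >= PROPENSITY_THRESHOLD:
            flag[j] = True
            j += 1
        j = start - 1
        while j >= 0 and p[j : j + 4].mean() >= PROPENSITY_THRESHOLD:
            flag[j] = True
            j -= 1
    return flag


def chou_fasman(sequence: str) -> np.ndarray:
    """Per-residue secondary-structure classes for a peptide.

    Returns an integer vector over {0: helix, 1: sheet, 2: turn, 3: coil}
    of the same length as ``sequence``.
    """
    validate_sequence(sequence)
    tab = PROPENSITY_TABLE
    ph = np.array([tab[a]["p_helix"] for a in sequence])
    ps = np.array([tab[a]["p_sheet"] for a in sequence])
    pt = np.array([tab[a]["p_turn"] for a in sequence])
    f0 = np.array([tab[a]["f_i"] for a in sequence])
    f1 = np.array([tab[a]["f_i1"] for a in sequence])
    f2 = np.array([tab[a]["f_i2"] for a in sequence])
    f3 = np.array([tab[a]["f_i3"] for a in sequence])
    n = len(sequence)

    helix = _nucleate_extend(ph, window=6, min_hits=4)
    sheet = _nucleate_extend(ps, window=5, min_hits=3)

    out = np.full(n, COIL, dtype=np.int64)
    out[helix & ~sheet] = HELIX
    out[sheet & ~helix] = SHEET
    for start, stop in _runs(helix & sheet):
        winner = HELIX if ph[start:stop].mean() >= ps[start:stop].mean() else SHEET
        out[start:stop] = winner

    for i in range(n - 3):
        if f0[i] * f1[i + 1] * f2[i + 2] * f3[i + 3] > TURN_PRODUCT_THRESHOLD:
            mpt = pt[i : i + 4].mean()
            if (
                mpt > PROPENSITY_THRESHOLD
                and mpt > ph[i : i + 4].mean()
                and mpt > ps[i : i + 4].mean()
            ):
                out[i : i + 4] = TURN
    return out
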