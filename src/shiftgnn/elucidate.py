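"""Structure elucidation and misassignment screening from shift lists.

Candidate structures are ranked against an experimental spectrum by the
mean absolute error (MAE) between sorted predicted and sorted
experimental shift lists — for 1-to-1 matching under mean absolute
difference, pairing by rank is optimal, which the test suite verifies
against exhaustive permutation search.  A global mode assigns several
spectra to several candidates at once by minimizing the total MAE over
all spectrum-candidate pairings.  For assigned spectra, structures whose
as-assigned MAE exceeds a threshold (default 3.5 ppm, strict) are flagged
and the experimental values are optimally reordered over the atoms to
propose a corrected assignment.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment


@dataclass
class CandidateResult:
    """Sorted-matching comparison of one candidate against a spectrum."""

    candidate_id: str
    pairs: list[tuple[float, float]]  # (pred ppm, exp ppm), rank-matched
    mae: float
    abs_errors: np.ndarray
    tie: bool = False
    dropped: int = 0  # extreme values truncated in permissive mode


@dataclass
class ReassignmentResult:
    """Optimal reordering of assigned experimental shifts."""

    permutation: np.ndarray  # exp value assigned to pred atom k comes from exp[perm[k]]
    mae_before: float
    mae_after: float
    flagged: bool
    threshold: float = 3.5
    atom_ids: np.ndarray = field(default=None)


def match_sorted(
    pred, exp, candidate_id: str = "", allow_truncate: bool = False
) -> CandidateResult:
    """Compare shift lists by sorting both and pairing positionally.

    With ``allow_truncate`` unequal lengths are handled by pairing the
    sorted overlap after dropping the most extreme excess values from the
    longer list; by default unequal lengths are an error, since silent
    truncation can flip candidate rankings.
    """
    p = np.sort(np.asarray(pred, dtype=np.float64))
    e = np.sort(np.asarray(exp, dtype=np.float64))
    if p.size == 0 or e.size == 0:
        raise ValueError("empty shift list")
    dropped = 0
    if p.size != e.size:
        if not allow_truncate:
            raise ValueError(
                f"length mismatch: {p.size} predicted vs {e.size} experimental "
                "(pass allow_truncate=True to pair the sorted overlap)"
            )
        n = min(p.size, e.size)
        dropped = max(p.size, e.size) - n
        p, e = _best_sorted_overlap(p, e, n)
    errs = np.abs(p - e)
    return CandidateResult(
        candidate_id=candidate_id,
        pairs=list(zip(p.tolist(), e.tolist())),
        mae=float(errs.mean()),
        abs_errors=errs,
        dropped=dropped,
    )


def _best_sorted_overlap(p, e, n):
    """Choose the contiguous window of the longer sorted list minimizing MAE."""
    long, short = (p, e) if p.size > e.size else (e, p)
    best, best_mae = 0, np.inf
    for start in range(long.size - n + 1):
        mae = np.abs(long[start : start + n] - short).mean()
        if mae < best_mae:
            best, best_mae = start, mae
    window = long[best : best + n]
    return (window, short) if p.size > e.size else (short, window)


def rank_candidates(
    candidates: list[tuple[str, np.ndarray]],
    exp, *,
    mode: str = "rank",
    allow_truncate: bool = False,
) -> list[CandidateResult]:
    """Order candidate structures by sorted-matching MAE.

    ``candidates`` maps ids to predicted shift lists (e.g. ensemble final
    shifts).  ``exp`` is either one spectrum (mode="rank") or a list of
    spectra, one per candidate (mode="global"): the global mode finds the
    spectrum-candidate bijection minimizing the summed MAE, the cumulative
    criterion that rescues cases where per-spectrum argmin misassigns.
    Ties in MAE keep input order and are flagged.
    """
    if mode == "rank":
        results = [
            match_sorted(shifts, exp, cid, allow_truncate)
            for cid, shifts in candidates
        ]
        order = sorted(range(len(results)), key=lambda i: (results[i].mae, i))
        ranked = [results[i] for i in order]
        maes = [round(r.mae, 12) for r in ranked]
        for r in ranked:
            if maes.count(round(r.mae, 12)) > 1:
                r.tie = True
        return ranked
    if mode == "global":
        spectra = exp
        if len(spectra) != len(candidates):
            raise ValueError("global mode needs one spectrum per candidate")
        cost = np.array(
            [
                [match_sorted(shifts, s, cid, allow_truncate).mae for s in spectra]
                for cid, shifts in candidates
            ]
        )
        rows, cols = linear_sum_assignment(cost)
        out = []
        for i, j in zip(rows, cols):
            cid, shifts = candidates[i]
            r = match_sorted(shifts, spectra[j], cid, allow_truncate)
            r.candidate_id = f"{cid}<-spectrum{j}"
            out.append(r)
        return out
    raise ValueError(f"unknown mode {mode!r}")


def optimal_reassignment(
    pred, exp, atom_ids=None, threshold: float = 3.5, classes=None
) -> ReassignmentResult:
    """Reorder assigned experimental shifts to minimize MAE against predictions.

    ``pred`` and ``exp`` are aligned per-atom arrays (the as-assigned
    pairing).  Unconstrained, the optimum is rank matching: sort both and
    pair by rank.  With ``classes`` (one hashable label per atom, e.g.
    CH-multiplicity), swaps are restricted to within-class and solved as a
    square assignment problem.  ``flagged`` is True iff the as-assigned
    MAE strictly exceeds ``threshold``.
    """
    p = np.asarray(pred, dtype=np.float64)
    e = np.asarray(exp, dtype=np.float64)
    if p.shape != e.shape or p.ndim != 1:
        raise ValueError("pred and exp must be equal-length 1-D arrays")
    if p.size == 0:
        raise ValueError("empty shift lists")
    mae_before = float(np.abs(p - e).mean())
    if classes is None:
        perm = np.empty(p.size, dtype=np.int64)
        perm[np.argsort(p, kind="stable")] = np.argsort(e, kind="stable")
    else:
        classes = np.asarray(classes)
        if classes.shape != p.shape:
            raise ValueError("classes must align with atoms")
        cost = np.abs(p[:, None] - e[None, :])
        cost[classes[:, None] != classes[None, :]] = 1e9
        _, perm = linear_sum_assignment(cost)
    mae_after = float(np.abs(p - e[perm]).mean())
    return ReassignmentResult(
        permutation=perm,
        mae_before=mae_before,
        mae_after=mae_after,
        flagged=mae_before > threshold,
        threshold=threshold,
        atom_ids=None if atom_ids is None else np.asarray(atom_ids),
    )


def flag_outliers(
    results: list[CandidateResult], threshold: float = 3.5
) -> list[CandidateResult]:
    """Structures whose MAE strictly exceeds ``threshold`` ppm."""
    return [r for r in results if r.mae > threshold]
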