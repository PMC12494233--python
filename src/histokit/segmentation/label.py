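"""Label-image post-processing: boundary tracing and cleaning.

Objects are 8-connected (background 4-connected).  All coordinates are
0-based (row, col).
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage as ndi

__all__ = ["trace_object_boundaries", "clean_label_image"]

# 8-neighbor offsets in clockwise screen order starting at West.
_CLOCKWISE = [(0, -1), (-1, -1), (-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1)]
_OFFSET_INDEX = {off: i for i, off in enumerate(_CLOCKWISE)}

_S8 = np.ones((3, 3), dtype=int)


def _trace_single(mask: np.ndarray):
    """Moore-neighbor trace of one 8-connected object (boolean mask).

    Returns the closed clockwise boundary starting at the topmost-then-
    leftmost pixel.  Uses Jacob's stopping criterion (return to the start
    pixel entered from the same direction).
    """
    rows, cols = np.nonzero(mask)
    order = np.lexsort((cols, rows))
    start = (int(rows[order[0]]), int(cols[order[0]]))

    def at(p):
        r, c = p
        return 0 <= r < mask.shape[0] and 0 <= c < mask.shape[1] and mask[r, c]

    if not any(at((start[0] + dr, start[1] + dc)) for dr, dc in _CLOCKWISE):
        return [start]

    boundary = [start]
    backtrack = (start[0], start[1] - 1)  # entered from the west
    current = start
    first_state = (current, backtrack)
    limit = 4 * mask.sum() + 8
    steps = 0
    while steps < limit:
        steps += 1
        rel = (backtrack[0] - current[0], backtrack[1] - current[1])
        k = _OFFSET_INDEX[rel]
        moved = False
        for j in range(1, 9):
            dr, dc = _CLOCKWISE[(k + j) % 8]
            cand = (current[0] + dr, current[1] + dc)
            if at(cand):
                prev_dr, prev_dc = _CLOCKWISE[(k + j - 1) % 8]
                backtrack = (current[0] + prev_dr, current[1] + prev_dc)
                current = cand
                moved = True
                break
        if not moved:  # isolated pixel (shouldn't happen past the guard)
            break
        if (current, backtrack) == first_state:
            break
        boundary.append(current)
    # drop the duplicated closing start pixel if present
    if len(boundary) > 1 and boundary[-1] == start:
        boundary.pop()
    return boundary


def trace_object_boundaries(labels, connectivity: int = 8):
    """Trace a closed clockwise boundary for every labeled object.

    Parameters
    ----------
    labels : (H, W) int array
        Label image; 0 is background.
    connectivity : {4, 8}
        Neighborhood used to find the object's pixels before tracing;
        tracing itself walks the Moore (8-) neighborhood.

    Returns
    -------
    dict mapping label id -> list of (row, col) tuples, ordered
    clockwise, starting at the topmost-then-leftmost boundary pixel.
    Single-pixel objects yield a one-point boundary.
    """
    labels = np.asarray(labels)
    if connectivity not in (4, 8):
        raise ValueError("connectivity must be 4 or 8")
    out = {}
    objects = ndi.find_objects(labels)
    for idx, sl in enumerate(objects, start=1):
        if sl is None:
            continue
        sub = labels[sl] == idx
        pts = _trace_single(sub)
        r0, c0 = sl[0].start, sl[1].start
        out[idx] = [(r + r0, c + c0) for r, c in pts]
    return out


def _spur_pass(mask: np.ndarray) -> bool:
    """Remove one layer of 1-px protrusions in-place; True if changed."""
    nb = ndi.convolve(mask.astype(int), _S8, mode="constant") - mask.astype(int)
    cand = np.argwhere(mask & (nb > 0) & (nb < 3))
    changed = False
    for r, c in cand:
        neigh = []
        for dr, dc in _CLOCKWISE:
            rr, cc = r + dr, c + dc
            if 0 <= rr < mask.shape[0] and 0 <= cc < mask.shape[1] and mask[rr, cc]:
                neigh.append((rr, cc))
        if not neigh or len(neigh) >= 3:
            continue
        if len(neigh) == 2:
            (r1, c1), (r2, c2) = neigh
            if max(abs(r1 - r2), abs(c1 - c2)) > 1:
                continue  # removal would disconnect the two neighbors
        mask[r, c] = False
        changed = True
    return changed


def clean_label_image(labels, min_area: int = 0, remove_border: bool = False,
                      remove_spurs: bool = False):
    """Remove small objects, border-touching objects, and 1-px spurs.

    Spur removal iteratively deletes pixels with fewer than three
    8-neighbors whose removal does not locally disconnect the object
    (so tails peel back to the body one endpoint at a time).  Surviving
    objects are relabeled 1..n in the order of their original ids.
    """
    if min_area < 0:
        raise ValueError("min_area must be >= 0")
    labels = np.asarray(labels).copy()

    if remove_border:
        border_ids = np.unique(
            np.concatenate([labels[0], labels[-1], labels[:, 0], labels[:, -1]])
        )
        labels[np.isin(labels, border_ids[border_ids > 0])] = 0

    if remove_spurs:
        for idx in np.unique(labels):
            if idx == 0:
                continue
            m = labels == idx
            while _spur_pass(m):
                pass
            labels[(labels == idx) & ~m] = 0

    if min_area > 0:
        ids, counts = np.unique(labels[labels > 0], return_counts=True)
        labels[np.isin(labels, ids[counts < min_area])] = 0

    survivors = np.unique(labels[labels > 0])
    remap = np.zeros(labels.max() + 1 if labels.size else 1, dtype=labels.dtype)
    remap[survivors] = np.arange(1, survivors.size + 1)
    return remap[labels]
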