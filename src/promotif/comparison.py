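"""Motif similarity by symmetrised Kullback-Leibler distance.

The distance between two PWMs is minimised over all ungapped column offsets
with at least ``min_overlap`` overlapping columns and over both orientations
of the second motif:

    d = (1 / 2m) * sum_cols sum_base [ a log(a/b) + b log(b/a) ]

over the m overlapping columns, probabilities floored at 1e-6 before the
logs.  The result is symmetric, non-negative, and zero for identical PWMs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_formats import MotifLibrary
from .pwm import PWM

EPSILON = 1e-6


@dataclass
class MotifMatch:
    query_id: str
    reference_id: str
    distance: float
    offset: int
    orientation: str  # "forward" | "reverse_complement"
    matched_columns: int

    def __post_init__(self) -> None:
        if self.distance < -1e-12:
            raise ValueError("distance must be non-negative")
        self.distance = max(self.distance, 0.0)


def _sym_kl_columns(a: np.ndarray, b: np.ndarray) -> float:
    """Mean symmetrised KL over aligned columns (already overlapping)."""
    a = np.maximum(a, EPSILON)
    b = np.maximum(b, EPSILON)
    log_ratio = np.log(a / b)
    per_col = np.sum(a * log_ratio - b * log_ratio, axis=1)
    m = a.shape[0]
    return float(per_col.sum() / (2 * m))


def kl_distance(a: PWM, b: PWM, min_overlap: int = 4) -> MotifMatch:
    """Best (offset, orientation) symmetrised-KL match between two PWMs.

    ``offset`` is the column index in ``a`` aligned with column 0 of ``b``
    (negative when ``b`` starts before ``a``).
    """
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")
    if min_overlap > min(a.width, b.width):
        raise ValueError(
            f"min_overlap {min_overlap} exceeds the smaller motif width "
            f"{min(a.width, b.width)}"
        )
    best: tuple[float, int, str, int] | None = None
    for orientation, b_mat in (
        ("forward", b.matrix),
        ("reverse_complement", b.reverse_complement().matrix),
    ):
        wb = b_mat.shape[0]
        for offset in range(-(wb - min_overlap), a.width - min_overlap + 1):
            a_lo = max(0, offset)
            a_hi = min(a.width, offset + wb)
            m = a_hi - a_lo
            if m < min_overlap:
                continue
            b_lo = a_lo - offset
            d = _sym_kl_columns(a.matrix[a_lo:a_hi], b_mat[b_lo : b_lo + m])
            key = (d, abs(offset), orientation, -m)
            if best is None or key < best[0]:
                best = (key, offset, orientation, m)
    assert best is not None
    (d, _, _, _), offset, orientation, m = best
    return MotifMatch(
        query_id=a.motif_id,
        reference_id=b.motif_id,
        distance=d,
        offset=offset,
        orientation=orientation,
        matched_columns=m,
    )


def annotate_against_library(
    valid_groups,
    library: MotifLibrary,
    distance_cutoff: float = 0.3,
    min_overlap: int = 4,
) -> tuple[list[MotifMatch], list[str]]:
    """Match each valid motif group to its nearest library motif.

    Groups whose nearest neighbour lies within ``distance_cutoff`` are
    annotated with that motif's TF family; the rest are reported as
    unannotated candidates.  Assignment is independent of library order.
    """
    annotated: list[MotifMatch] = []
    unannotated: list[str] = []
    for group in valid_groups:
        pwm = group.representative if hasattr(group, "representative") else group
        gid = getattr(group, "group_id", None) or pwm.motif_id
        best: MotifMatch | None = None
        for entry in library:
            mo = min(min_overlap, pwm.width, entry.pwm.width)
            match = kl_distance(pwm, entry.pwm, min_overlap=mo)
            match.query_id = gid
            match.reference_id = entry.motif_id
            if (
                best is None
                or match.distance < best.distance
                or (match.distance == best.distance and match.reference_id < best.reference_id)
            ):
                best = match
        if best is not None and best.distance <= distance_cutoff:
            annotated.append(best)
        else:
            unannotated.append(gid)
    return annotated, unannotated


def write_annotation_tsv(
    annotated: list[MotifMatch], library: MotifLibrary, path: str
) -> None:
    family_of = {e.motif_id: e.tf_family for e in library}
    with open(path, "w") as fh:
        fh.write("group_id\treference_id\ttf_family\tdistance\toffset\torientation\n")
        for m in annotated:
            fh.write(
                f"{m.query_id}\t{m.reference_id}\t{family_of.get(m.reference_id, '?')}\t"
                f"{m.distance:.6g}\t{m.offset}\t{m.orientation}\n"
            )
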