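"""Inter-grader evaluation protocol: per-image SDs, mean-SD outlier
thresholds, marking-level outlier detection, image-elimination rules,
accuracy percentages and pairwise agreement counts.

The protocol judges every marking (six ophthalmologists, plus the algorithm
treated as a seventh marking) per parameter: a marking is an outlier when its
presence pushes the per-image sample SD of that parameter above the
parameter's mean-SD threshold. Images with concentrated outliers are
eliminated; an entity is accurate on a tested image when none of its
markings are flagged on any analysis parameter.
"""

from __future__ import annotations

import math
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from .core import ALGORITHM_ID, MANUAL_GRADERS, MarkingTable, ValidationError

PARAM_IDS = ("disc_area", "disc_centroid", "cup_area", "cup_centroid", "hcdr", "vcdr")

#: parameter sets per analysis: HCDR screening uses five parameters, VCDR
#: swaps the ratio, the final consolidated analysis uses all six
ANALYSES = {
    "hcdr": ("disc_area", "disc_centroid", "cup_area", "cup_centroid", "hcdr"),
    "vcdr": ("disc_area", "disc_centroid", "cup_area", "cup_centroid", "vcdr"),
    "final": PARAM_IDS,
}

#: ratio-parameter mean-SD threshold printed by the screening protocol
CDR_SD_THRESHOLD = 0.075

_CENTROID_PARAMS = ("disc_centroid", "cup_centroid")


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Decimal round-half-up (matches how the protocol prints percentages)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def sample_sd(values) -> float:
    """Unbiased (n-1 denominator) sample standard deviation."""
    values = np.asarray(list(values), dtype=float)
    if values.size < 2:
        raise ValidationError("sample SD needs at least 2 values")
    return float(np.std(values, ddof=1))


def centroid_sd(points) -> float:
    """Euclidean norm of the per-coordinate sample SDs of 2-D points."""
    pts = np.asarray(list(points), dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 2 or pts.shape[1] != 2:
        raise ValidationError("centroid SD needs at least 2 (row, col) points")
    return float(np.hypot(np.std(pts[:, 0], ddof=1), np.std(pts[:, 1], ddof=1)))


def _grader_key(g: str):
    return (0, int(g)) if str(g).isdigit() else (1, str(g))


def _sd_of(values: dict, is_point: bool) -> float:
    return centroid_sd(values.values()) if is_point else sample_sd(values.values())


def _mean_of(values: dict, is_point: bool):
    arr = np.asarray(list(values.values()), dtype=float)
    return arr.mean(axis=0)


def detect_outliers(values: dict, threshold: float, is_point: bool = False) -> set:
    """Iterative leave-one-out outlier detection for one image and parameter.

    While the SD of the remaining markings exceeds ``threshold`` and more than
    three remain, the marking whose removal most reduces the SD is flagged and
    removed (ties: larger absolute deviation from the current mean, then lower
    grader id). The remaining set never shrinks below three markings.
    """
    if len(values) < 3:
        raise ValidationError("outlier detection needs at least 3 markings")
    remaining = dict(values)
    flagged: set = set()
    while len(remaining) > 3 and _sd_of(remaining, is_point) > threshold:
        mean = _mean_of(remaining, is_point)
        best, best_key = None, None
        for g in remaining:
            rest = {h: v for h, v in remaining.items() if h != g}
            sd_rest = _sd_of(rest, is_point)
            dev = np.linalg.norm(np.asarray(remaining[g], dtype=float) - mean)
            key = (round(sd_rest, 12), -round(dev, 12), _grader_key(g))
            if best_key is None or key < best_key:
                best, best_key = g, key
        flagged.add(best)
        del remaining[best]
    return flagged


def mean_sd_thresholds(
    markings: MarkingTable,
    cdr_override: float | None = CDR_SD_THRESHOLD,
) -> dict:
    """Per-parameter thresholds: the mean over images of the per-image SD
    among the six manual graders. The two ratio thresholds default to the
    protocol constant 0.075 (pass ``cdr_override=None`` to keep the data-driven
    means instead)."""
    frame = markings.frame
    manual = frame[frame["grader_id"].isin(MANUAL_GRADERS)]
    out = {}
    for p in PARAM_IDS:
        sds = []
        for _, grp in manual.groupby("image_id"):
            if len(grp) < 2:
                continue
            if p in _CENTROID_PARAMS:
                pts = grp[[f"{p}_row", f"{p}_col"]].to_numpy(dtype=float)
                sds.append(centroid_sd(pts))
            else:
                vals = grp[p].to_numpy(dtype=float)
                if np.isnan(vals).any():
                    vals = vals[~np.isnan(vals)]
                    if vals.size < 2:
                        continue
                sds.append(sample_sd(vals))
        out[p] = float(np.mean(sds)) if sds else 0.0
    if cdr_override is not None:
        out["hcdr"] = cdr_override
        out["vcdr"] = cdr_override
    return out


def _param_values(frame: pd.DataFrame, param: str) -> dict:
    """grader -> value (float or (row, col)) for one image's sub-frame."""
    out = {}
    for _, row in frame.iterrows():
        g = row["grader_id"]
        if param in _CENTROID_PARAMS:
            out[g] = (float(row[f"{param}_row"]), float(row[f"{param}_col"]))
        else:
            v = float(row[param])
            if math.isnan(v):
                continue
            out[g] = v
    return out


def eliminate_image(flag_counts: dict) -> bool:
    """Image-elimination rules on per-parameter outlier counts.

    Eliminate when one parameter collects at least three outliers, or when
    there are at least four outliers overall with at least two sharing a
    parameter; three outliers spread over three distinct parameters keep the
    image.
    """
    counts = [c for c in flag_counts.values() if c > 0]
    if not counts:
        return False
    if max(counts) >= 3:
        return True
    if sum(counts) >= 4 and max(counts) >= 2:
        return True
    return False


def evaluate_entity(
    markings: MarkingTable,
    entity: str,
    params: tuple = ANALYSES["final"],
    thresholds: dict | None = None,
    not_localized: set = frozenset(),
) -> pd.DataFrame:
    """Per-image verdicts for one grader or the algorithm.

    Outlier detection runs over the six manual markings; when ``entity`` is
    the algorithm, its value joins as a seventh marking (and its flags count
    toward the elimination rules for its own evaluation). Not-localized
    images are excluded from testing. Returns a frame indexed by image with
    columns ``tested``, ``accurate``, ``eliminated`` and ``n_flags``.
    """
    thresholds = thresholds or mean_sd_thresholds(markings)
    frame = markings.frame
    present = set(frame["grader_id"])
    if entity not in present:
        raise ValidationError(f"entity {entity!r} absent from the marking table")
    detection_ids = set(MANUAL_GRADERS) | ({entity} if entity == ALGORITHM_ID else set())

    records = []
    for image_id, grp in frame.groupby("image_id"):
        if image_id in not_localized:
            records.append({"image_id": image_id, "tested": False, "accurate": False,
                            "eliminated": False, "n_flags": 0})
            continue
        sub = grp[grp["grader_id"].isin(detection_ids)]
        flag_counts, entity_flags = {}, 0
        for p in params:
            values = _param_values(sub, p)
            if len(values) < 3:
                flag_counts[p] = 0
                continue
            flags = detect_outliers(values, thresholds[p], is_point=p in _CENTROID_PARAMS)
            flag_counts[p] = len(flags)
            if entity in flags:
                entity_flags += 1
        eliminated = eliminate_image(flag_counts)
        tested = not eliminated
        records.append({
            "image_id": image_id,
            "tested": tested,
            "accurate": tested and entity_flags == 0,
            "eliminated": eliminated,
            "n_flags": entity_flags,
        })
    return pd.DataFrame(records).set_index("image_id")


def accuracy_table(
    markings: MarkingTable,
    thresholds: dict | None = None,
    analysis: str = "final",
    not_localized: set = frozenset(),
) -> pd.DataFrame:
    """Accuracy summary per grader and algorithm for one analysis.

    Rows: total, removed (eliminated), not_localized, tested, accurate and
    percentage (half-up, one decimal). Columns follow grader order with the
    algorithm last when present.
    """
    params = ANALYSES[analysis]
    thresholds = thresholds or mean_sd_thresholds(markings)
    entities = markings.graders()
    n_total = len(markings.images())
    cols = {}
    for e in entities:
        verdicts = evaluate_entity(markings, e, params, thresholds, not_localized)
        tested = int(verdicts["tested"].sum())
        accurate = int(verdicts["accurate"].sum())
        cols[e] = {
            "total": n_total,
            "removed": int(verdicts["eliminated"].sum()),
            "not_localized": len(not_localized),
            "tested": tested,
            "accurate": accurate,
            "percentage": accuracy_percentage(accurate, tested),
        }
    return pd.DataFrame(cols)


def accuracy_percentage(accurate: int, tested: int) -> float:
    if tested == 0:
        return 0.0
    return round_half_up(100.0 * accurate / tested, 1)


def agreement_matrix(
    markings: MarkingTable,
    thresholds: dict | None = None,
    analysis: str = "final",
    not_localized: set = frozenset(),
) -> pd.DataFrame:
    """Symmetric entity-by-entity matrix of co-accepted image counts.

    Entry (a, b) counts images on which both entities are unflagged on every
    analysis parameter and the image is neither eliminated nor unlocalized
    for either; the diagonal carries the total image count.
    """
    params = ANALYSES[analysis]
    thresholds = thresholds or mean_sd_thresholds(markings)
    entities = markings.graders()
    n_total = len(markings.images())
    accepted = {
        e: evaluate_entity(markings, e, params, thresholds, not_localized)["accurate"]
        for e in entities
    }
    mat = pd.DataFrame(index=entities, columns=entities, dtype=float)
    for a in entities:
        for b in entities:
            if a == b:
                mat.loc[a, b] = n_total
            else:
                mat.loc[a, b] = int((accepted[a] & accepted[b]).sum())
    return mat.astype(int)


def agreement_totals(matrix: pd.DataFrame) -> pd.Series:
    """Per-entity total agreements: row sum excluding the diagonal."""
    return matrix.sum(axis=1) - pd.Series(np.diag(matrix), index=matrix.index)
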