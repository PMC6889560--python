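"""Observer-study harness for registration-mismatch detection.

For each subject's reference registration a set of rating cases is
prepared: a number of unchanged (reference) presentations plus replicated
presentations with deliberate rigid registration errors.  The default
error set is the 12 combinations of {translation, rotation} x
{+/-0.5, +/-1.0, +/-2.0} (mm or degrees) about one configurable axis; with
24 references and 3 replicates per error this gives 60 cases per subject,
180 for three subjects.  Raters accept or decline each presented
registration; the analysis bins correct/wrong ratings per introduced error
magnitude, error type and subject.

The harness generates cases and analyzes ratings; modeling human observer
sensitivity/specificity is out of scope.  A threshold-based simulated
rater is provided purely to exercise the harness end to end.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from .drr import VoxelVolume, render_drr
from .geometry import RigidPose, compose
from .registration import VerificationViews, verification_views

_DEFAULT_MAGNITUDES = (0.5, 1.0, 2.0)


@dataclass(frozen=True)
class MismatchErrorSpec:
    """One deliberate registration error: a signed translation (mm) or
    rotation (degrees) about a single fixed axis."""
    type: str          # {translation, rotation}
    magnitude: float   # signed, mm or deg
    axis: str = "x"    # {x, y, z}

    def __post_init__(self):
        if self.type not in ("translation", "rotation"):
            raise ValueError(f"unknown error type {self.type!r}")
        if self.axis not in "xyz":
            raise ValueError(f"unknown axis {self.axis!r}")

    def delta_pose(self) -> RigidPose:
        v = [0.0] * 6
        i = "xyz".index(self.axis)
        v[i if self.type == "translation" else 3 + i] = self.magnitude
        return RigidPose.from_vector(v)


def default_error_set(translation_axis: str = "x",
                      rotation_axis: str = "x",
                      magnitudes: Sequence[float] = _DEFAULT_MAGNITUDES
                      ) -> List[MismatchErrorSpec]:
    """The 12 default error specs: six translational and six rotational,
    +/- each magnitude, applied about a single configurable axis
    (default: the lateral axis)."""
    out = []
    for m in magnitudes:
        for s in (+1.0, -1.0):
            out.append(MismatchErrorSpec("translation", s * m, translation_axis))
            out.append(MismatchErrorSpec("rotation", s * m, rotation_axis))
    return out


@dataclass
class RegistrationCase:
    """One registration presented for rating: a subject's reference pose,
    optionally corrupted by a deliberate error."""
    case_id: str
    subject_id: str
    reference_pose: RigidPose
    error: Optional[MismatchErrorSpec]
    order_index: int

    @property
    def presented_pose(self) -> RigidPose:
        if self.error is None:
            return self.reference_pose
        return compose(self.error.delta_pose(), self.reference_pose)

    @property
    def is_reference(self) -> bool:
        return self.error is None


@dataclass
class RatingRecord:
    """One accept/decline decision on a presented registration."""
    case_id: str
    user_id: str
    decision: str  # {accept, decline}
    correct: bool

    def __post_init__(self):
        if self.decision not in ("accept", "decline"):
            raise ValueError(f"decision must be accept/decline, got {self.decision!r}")


def make_rating_record(case: RegistrationCase, user_id: str,
                       decision: str) -> RatingRecord:
    """Build a record with its correctness derived from the case: accepting
    a reference or declining a defective registration is correct."""
    correct = (decision == "accept") if case.is_reference else (decision == "decline")
    return RatingRecord(case_id=case.case_id, user_id=user_id,
                        decision=decision, correct=correct)


def generate_mismatch_cases(subject_poses: Dict[str, RigidPose] | Sequence[RigidPose],
                            error_set: Optional[Sequence[MismatchErrorSpec]] = None,
                            n_reference: int = 24,
                            reps_per_error: int = 3,
                            seed: int = 0) -> List[RegistrationCase]:
    """Prepare the per-subject rating case lists with a seeded, shuffled
    presentation order.

    Defaults yield 24 + 3*12 = 60 cases per subject (each of the 12 error
    specs appearing exactly three times) and 180 cases for three subjects.
    """
    if not isinstance(subject_poses, dict):
        subject_poses = {f"subject{i}": p for i, p in enumerate(subject_poses)}
    if len(subject_poses) == 0:
        raise ValueError("at least one subject pose is required")
    if error_set is None:
        error_set = default_error_set()
    rng = np.random.default_rng(seed)
    cases: List[RegistrationCase] = []
    for subject_id, ref_pose in subject_poses.items():
        errors: List[Optional[MismatchErrorSpec]] = [None] * n_reference
        for spec in error_set:
            errors.extend([spec] * reps_per_error)
        order = rng.permutation(len(errors))
        for k, j in enumerate(order):
            cases.append(RegistrationCase(
                case_id=f"{subject_id}_case{k:03d}",
                subject_id=subject_id,
                reference_pose=ref_pose,
                error=errors[j],
                order_index=k))
    return cases


def render_rating_pair(case: RegistrationCase,
                       ct: VoxelVolume,
                       xray_pair: Sequence,
                       geometries: Sequence,
                       step_mm: Optional[float] = None,
                       metric: str = "ncc") -> List[VerificationViews]:
    """Render the verification composites (blend/split/checker + residual
    score) of each X-ray against the DRR at the case's presented pose."""
    out = []
    for xray, geom in zip(xray_pair, geometries):
        try:
            drr = render_drr(ct, geom, pose=case.presented_pose, step_mm=step_mm)
            out.append(verification_views(xray, drr, metric=metric))
        except Exception as exc:
            raise RuntimeError(
                f"rendering failed for case {case.case_id}") from exc
    return out


def threshold_rater(cases: Sequence[RegistrationCase],
                    residual_scores: Dict[str, float],
                    reference_score: float,
                    drop_threshold: float,
                    user_id: str = "sim") -> List[RatingRecord]:
    """A simulated rater that declines whenever the residual similarity
    falls more than ``drop_threshold`` below the reference score.  Exists
    to exercise the harness, not to model human raters."""
    records = []
    for case in cases:
        score = residual_scores[case.case_id]
        decision = "decline" if (reference_score - score) > drop_threshold else "accept"
        records.append(make_rating_record(case, user_id, decision))
    return records


def analyze_ratings(records: Sequence[RatingRecord],
                    cases: Sequence[RegistrationCase]) -> pd.DataFrame:
    """Histogram table behind the rating-results figures: counts and
    fractions of correct vs wrong ratings per introduced-error magnitude
    bin (signed; 0 = reference), error type and subject."""
    by_id = {c.case_id: c for c in cases}
    rows = []
    for rec in records:
        case = by_id.get(rec.case_id)
        if case is None:
            raise KeyError(f"rating references unknown case_id {rec.case_id!r}")
        rows.append({
            "subject": case.subject_id,
            "user": rec.user_id,
            "error_type": case.error.type if case.error else "none",
            "magnitude": case.error.magnitude if case.error else 0.0,
            "correct": rec.correct,
        })
    df = pd.DataFrame(rows)
    g = (df.groupby(["subject", "error_type", "magnitude"])["correct"]
           .agg(n_total="count", n_correct="sum").reset_index())
    g["n_wrong"] = g["n_total"] - g["n_correct"]
    g["frac_wrong"] = g["n_wrong"] / g["n_total"]
    return g
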