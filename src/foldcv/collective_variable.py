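"""Relative residue/segment folding degree collective variables.

A residue's similarity to a reference conformation is scored by the rational
switching function

    RCS_rel = (1 - x^m) / (1 - x^n),   x = (RCS - RCS_ref) / RCS_tol,

with positive even exponents m < n (defaults m=2, n=4, for which the
expression simplifies exactly to 1/(1 + x^2)).  The function peaks at 1 when
RCS equals the reference, takes the value m/n at |x| = 1 and decays towards
0 away from the reference.  The relative segment folding degree SCS of a
segment kappa (a consecutive residue range) is the mean of the per-residue
values; with the default exponents it lies in (0, 1].

The default reference (RCS_ref = 7.273, RCS_tol = 0.421) is the survey mean
and s.d. of the residue folding degree for the alpha-helix (H) category, so
the default CV measures alpha-helical content.  Alternative reference modes
derive per-residue (RCS_ref, RCS_tol) pairs from a reference structure
(segment mean or per-residue) or from per-category survey statistics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from foldcv.constants import CATEGORY_TABLE
from foldcv.errors import SegmentError
from foldcv.folding_degree import FoldingProfile, rcs_profile, rcs_profile_from_records
from foldcv.structure_io import BackboneChain, DihedralRecord

__all__ = [
    "SwitchingParams",
    "HELICALITY",
    "SegmentDefinition",
    "CVSeries",
    "rcs_rel",
    "scs_rel",
    "make_reference",
    "ideal_motif_table",
    "cv_timeseries",
]


@dataclass(frozen=True)
class SwitchingParams:
    """Reference value, tolerance and exponents of the switching function."""

    rcs_ref: float = 7.273
    rcs_tol: float = 0.421
    m: int = 2
    n: int = 4

    def __post_init__(self):
        if not self.rcs_tol > 0:
            raise ValueError("rcs_tol must be positive")
        for e in (self.m, self.n):
            if e <= 0 or e % 2:
                raise ValueError("exponents m, n must be positive even integers")
        if not self.m < self.n:
            raise ValueError("require m < n")


#: Alpha-helicality preset: H-category survey mean and s.d.
HELICALITY = SwitchingParams()


@dataclass(frozen=True)
class SegmentDefinition:
    """A consecutive residue range (inclusive, 1-based numbers) in a chain."""

    name: str
    chain_id: str
    start: int
    end: int

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError("segment start must not exceed end")

    def __len__(self) -> int:
        return self.end - self.start + 1

    def resnums(self) -> range:
        return range(self.start, self.end + 1)


def rcs_rel(rcs, params: SwitchingParams = HELICALITY):
    """Relative residue folding degree (switching function of RCS).

    Accepts a scalar or array of RCS values.  Continuous everywhere: the
    removable singularity at |x| = 1 evaluates to the limit m/n.
    """
    x = (np.asarray(rcs, dtype=float) - params.rcs_ref) / params.rcs_tol
    if params.m == 2 and params.n == 4:
        out = 1.0 / (1.0 + x * x)
    else:
        xm = x**params.m
        xn = x**params.n
        with np.errstate(divide="ignore", invalid="ignore"):
            out = np.where(xn == 1.0, params.m / params.n, (1.0 - xm) / (1.0 - xn))
    if np.ndim(rcs) == 0:
        return float(out)
    return out


def _params_for_segment(
    params, segment: SegmentDefinition
) -> list[SwitchingParams]:
    """Normalize a params spec to one SwitchingParams per segment residue."""
    if isinstance(params, SwitchingParams):
        return [params] * len(segment)
    params = list(params)
    if len(params) != len(segment):
        raise SegmentError(
            f"got {len(params)} parameter sets for a {len(segment)}-residue segment"
        )
    return params


def scs_rel(
    profile: FoldingProfile,
    segment: SegmentDefinition,
    params=HELICALITY,
) -> float:
    """Relative segment folding degree: segment mean of rcs_rel.

    ``params`` is a single SwitchingParams shared by every residue or a
    per-residue sequence.  Raises SegmentError if any residue of the segment
    has an undefined folding degree.
    """
    plist = _params_for_segment(params, segment)
    vals = []
    for resnum, p in zip(segment.resnums(), plist):
        try:
            r = profile.rcs_at(resnum)
        except KeyError as exc:
            raise SegmentError(str(exc)) from exc
        if math.isnan(r):
            raise SegmentError(
                f"residue {resnum} in segment {segment.name!r} has undefined RCS"
            )
        vals.append(rcs_rel(r, p))
    return float(np.mean(vals))


def make_reference(
    mode: str,
    segment: SegmentDefinition,
    reference_profile: FoldingProfile | None = None,
    labels: Mapping[int, str] | None = None,
    tol: float = 1.0,
    m: int = 2,
    n: int = 4,
    use_category_sd: bool = False,
    category_table: pd.DataFrame = CATEGORY_TABLE,
) -> list[SwitchingParams]:
    """Per-residue switching parameters for a segment.

    Modes
    -----
    ``helicality``
        The H-category preset (ref 7.273, tol 0.421) for every residue.
    ``segment_mean``
        One shared reference: the mean reference-structure RCS over the
        segment.
    ``per_residue``
        Each residue's own reference-structure RCS.
    ``category``
        The survey mean RCS of the residue's secondary-structure category in
        the reference structure (``labels`` maps residue number to
        category); the tolerance is the category s.d. when
        ``use_category_sd`` is set, else ``tol``.

    ``tol`` (default 1.0) is the tolerance for the structure-derived modes.
    """
    if mode == "helicality":
        return [SwitchingParams(m=m, n=n)] * len(segment)
    if mode == "category":
        if labels is None:
            raise SegmentError("category mode requires per-residue SS labels")
        out = []
        for resnum in segment.resnums():
            if resnum not in labels:
                raise SegmentError(f"no SS label for residue {resnum}")
            cat = labels[resnum]
            if cat not in category_table.index:
                raise SegmentError(f"unknown SS category {cat!r}")
            row = category_table.loc[cat]
            out.append(
                SwitchingParams(
                    rcs_ref=float(row["rcs_mean"]),
                    rcs_tol=float(row["rcs_sd"]) if use_category_sd else tol,
                    m=m,
                    n=n,
                )
            )
        return out
    if mode in ("segment_mean", "per_residue"):
        if reference_profile is None:
            raise SegmentError(f"{mode} mode requires a reference profile")
        refs = []
        for resnum in segment.resnums():
            try:
                r = reference_profile.rcs_at(resnum)
            except KeyError as exc:
                raise SegmentError(str(exc)) from exc
            if math.isnan(r):
                raise SegmentError(
                    f"reference RCS undefined for residue {resnum}"
                )
            refs.append(r)
        if mode == "segment_mean":
            shared = float(np.mean(refs))
            return [SwitchingParams(shared, tol, m, n)] * len(segment)
        return [SwitchingParams(r, tol, m, n) for r in refs]
    raise ValueError(f"unknown reference mode {mode!r}")


def ideal_motif_table(
    params: SwitchingParams = HELICALITY,
    category_table: pd.DataFrame = CATEGORY_TABLE,
) -> pd.Series:
    """Switching-function value of each category's mean RCS.

    An "ideal" motif has every residue at the category's survey mean folding
    degree, so its segment value equals the per-residue value.  With the
    default helicality parameters the H entry is exactly 1 by construction.
    Values are full precision; round for display.
    """
    return pd.Series(
        {
            cat: rcs_rel(float(category_table.loc[cat, "rcs_mean"]), params)
            for cat in category_table.index
        },
        name="scs_rel",
    )


@dataclass
class CVSeries:
    """Per-frame, per-segment CV values.

    ``values`` has one row per frame and one column per segment; entries are
    NaN where a frame could not be evaluated, with the corresponding entry
    of ``flagged`` set.
    """

    values: pd.DataFrame
    flagged: pd.DataFrame = field(repr=False)

    def __len__(self) -> int:
        return len(self.values)

    def to_tsv(self, path) -> None:
        out = self.values.copy()
        out.insert(0, "frame", out.index)
        out.to_csv(path, sep="\t", index=False, na_rep="NA")


def _frame_profiles(frame, method: str) -> dict[str, FoldingProfile]:
    """Folding profiles keyed by chain id for one trajectory frame."""
    if isinstance(frame, BackboneChain):
        frame = [frame]
    if frame and isinstance(frame[0], DihedralRecord):
        return {"": rcs_profile_from_records(frame, method=method)}
    return {c.chain_id: rcs_profile(c, method=method) for c in frame}


def cv_timeseries(
    trajectory: Sequence,
    segments: Sequence[SegmentDefinition],
    references: Mapping[str, Sequence[SwitchingParams] | SwitchingParams],
    method: str = "block",
) -> CVSeries:
    """Evaluate segment CVs over a trajectory.

    ``trajectory`` is a sequence of frames; each frame is a BackboneChain, a
    list of BackboneChain (multi-chain), or a list of DihedralRecord.
    ``references`` maps segment name to its switching parameters.  Frames in
    which a segment has undefined residues yield NaN and are flagged rather
    than dropped.
    """
    for seg in segments:
        if seg.name not in references:
            raise SegmentError(f"no reference parameters for segment {seg.name!r}")
    names = [s.name for s in segments]
    rows = np.full((len(trajectory), len(segments)), np.nan)
    flags = np.zeros((len(trajectory), len(segments)), dtype=bool)
    for fi, frame in enumerate(trajectory):
        profiles = _frame_profiles(frame, method)
        for si, seg in enumerate(segments):
            key = seg.chain_id if seg.chain_id in profiles else ""
            if key not in profiles:
                raise SegmentError(
                    f"segment {seg.name!r}: chain {seg.chain_id!r} absent in frame {fi}"
                )
            try:
                rows[fi, si] = scs_rel(profiles[key], seg, references[seg.name])
            except SegmentError:
                flags[fi, si] = True
    return CVSeries(
        values=pd.DataFrame(rows, columns=names),
        flagged=pd.DataFrame(flags, columns=names),
    )
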