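"""Secondary-structure label ingestion and descriptive statistics.

Consumes per-residue category labels produced by DSSP (classic and 4.x
text output), STRIDE (ASG records) or a plain 3-column TSV, and computes
per-category folding-degree statistics, cross-algorithm confusion matrices
and motif (run) length histograms.  The label alphabet is the nine DSSP 4
categories H, G, I, E, B, T, S, P, C; a DSSP blank maps to C.  Secondary-
structure assignment itself is out of scope — only the algorithms' output
files are parsed.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from foldcv.constants import SS_CATEGORIES
from foldcv.errors import LabelError
from foldcv.folding_degree import FoldingProfile

__all__ = [
    "SSLabeling",
    "parse_labels",
    "category_stats",
    "agreement_matrix",
    "motif_lengths",
]


@dataclass
class SSLabeling:
    """Ordered per-residue secondary-structure labels.

    ``records`` is a list of (chain_id, resnum, category) in file order;
    ``source`` tags the producing algorithm/dialect.
    """

    records: list[tuple[str, int, str]]
    source: str = ""

    def __post_init__(self):
        seen = set()
        for chain, resnum, cat in self.records:
            if cat not in SS_CATEGORIES:
                raise LabelError(f"label {cat!r} outside the 9-category alphabet")
            key = (chain, resnum)
            if key in seen:
                raise LabelError(f"duplicate residue entry {key}")
            seen.add(key)

    def __len__(self) -> int:
        return len(self.records)

    def as_dict(self) -> dict[tuple[str, int], str]:
        return {(c, r): s for c, r, s in self.records}

    def chain_dict(self, chain_id: str) -> dict[int, str]:
        return {r: s for c, r, s in self.records if c == chain_id}


def _norm_label(raw: str) -> str:
    raw = raw.strip()
    if raw == "" or raw == "-":
        return "C"
    raw = raw.upper()
    if raw not in SS_CATEGORIES:
        raise LabelError(f"unknown SS label {raw!r}")
    return raw


def _parse_tsv(lines: Iterable[str]) -> list[tuple[str, int, str]]:
    records = []
    for ln, line in enumerate(lines, 1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise LabelError(f"line {ln}: expected 3 tab-separated columns")
        chain, resnum, label = parts[0].strip(), parts[1].strip(), parts[2]
        if ln == 1 and not _is_int(resnum):
            continue  # header row
        records.append((chain, int(resnum), _norm_label(label)))
    return records


def _is_int(s: str) -> bool:
    try:
        int(s)
        return True
    except ValueError:
        return False


def _parse_dssp(lines: Iterable[str]) -> list[tuple[str, int, str]]:
    """Classic DSSP column format (also emitted by DSSP 4 in dssp mode)."""
    records = []
    in_body = False
    for line in lines:
        if not in_body:
            if line.lstrip().startswith("#") and "RESIDUE" in line and "AA" in line:
                in_body = True
            continue
        if len(line) < 17:
            continue
        if line[13] == "!":  # chain break / chain terminator record
            continue
        resnum = line[5:10].strip()
        if not resnum:
            continue
        chain = line[11].strip() or " "
        records.append((chain, int(resnum), _norm_label(line[16])))
    if not records:
        raise LabelError("no residue records found (not DSSP output?)")
    return records


def _parse_stride(lines: Iterable[str]) -> list[tuple[str, int, str]]:
    """STRIDE ASG records: ASG resname chain resnum ordinal code ..."""
    records = []
    for line in lines:
        if not line.startswith("ASG"):
            continue
        parts = line.split()
        if len(parts) < 6:
            raise LabelError(f"malformed ASG record: {line.rstrip()}")
        chain = parts[2]
        resnum = int(parts[3])
        code = parts[5]
        if code == "b":  # STRIDE lowercase beta-bridge variant
            code = "B"
        records.append((chain, resnum, _norm_label(code)))
    if not records:
        raise LabelError("no ASG records found (not STRIDE output?)")
    return records


_DIALECTS = {
    "tsv": _parse_tsv,
    "dssp": _parse_dssp,
    "dssp4": _parse_dssp,
    "stride": _parse_stride,
}


def parse_labels(path, dialect: str) -> SSLabeling:
    """Parse a per-residue secondary-structure label file.

    ``dialect`` is one of ``dssp``, ``dssp4``, ``stride`` or ``tsv`` (a
    3-column chain/resnum/label table; blank labels mean C).
    """
    if dialect not in _DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}")
    path = Path(path)
    with path.open() as fh:
        records = _DIALECTS[dialect](fh)
    return SSLabeling(records=records, source=dialect)


def _profile_rcs_map(profiles) -> dict[tuple[str, int], float]:
    if isinstance(profiles, FoldingProfile):
        profiles = [profiles]
    out = {}
    for prof in profiles:
        for resnum, rcs in zip(prof.resnums, prof.rcs):
            out[(prof.chain_id, int(resnum))] = float(rcs)
    return out


def category_stats(labels: SSLabeling, profiles) -> pd.DataFrame:
    """Per-category statistics of the residue folding degree.

    ``profiles`` is a FoldingProfile or an iterable of them (one per chain).
    Residues without a defined RCS (termini, breaks) are excluded.  Returns
    a DataFrame indexed by category with count, mean, sample s.d. and
    quartiles; the s.d. is NaN for single-residue categories.
    """
    rcs_map = _profile_rcs_map(profiles)
    values: dict[str, list[float]] = {}
    for chain, resnum, cat in labels.records:
        r = rcs_map.get((chain, resnum), math.nan)
        if not math.isnan(r):
            values.setdefault(cat, []).append(r)
    if not values:
        raise LabelError("no labeled residue has a defined folding degree")
    rows = {}
    for cat, vals in values.items():
        arr = np.asarray(vals)
        rows[cat] = {
            "count": arr.size,
            "mean": arr.mean(),
            "sd": arr.std(ddof=1) if arr.size > 1 else np.nan,
            "q1": np.percentile(arr, 25),
            "median": np.percentile(arr, 50),
            "q3": np.percentile(arr, 75),
        }
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "category"
    df["count"] = df["count"].astype(int)
    return df.loc[[c for c in SS_CATEGORIES if c in df.index]]


def agreement_matrix(
    labels_a: SSLabeling, labels_b: SSLabeling
) -> tuple[pd.DataFrame, pd.Series]:
    """Confusion counts and per-category % disagreement between labelings.

    Both labelings must cover the same residue set.  Rows index the
    categories of ``labels_a`` (the declared reference), columns those of
    ``labels_b``.  The disagreement of category c is the percentage of
    residues labeled c by the reference that receive a different label from
    ``labels_b`` (NaN for categories the reference never assigns).
    """
    a = labels_a.as_dict()
    b = labels_b.as_dict()
    if set(a) != set(b):
        raise LabelError("labelings cover different residue sets")
    counts = pd.DataFrame(
        0, index=list(SS_CATEGORIES), columns=list(SS_CATEGORIES), dtype=int
    )
    for key, ca in a.items():
        counts.loc[ca, b[key]] += 1
    row_tot = counts.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        disagree = 100.0 * (row_tot - np.diag(counts)) / row_tot
    disagree[row_tot == 0] = np.nan
    disagree.name = "pct_disagreement"
    return counts, disagree


def motif_lengths(labels: SSLabeling) -> dict[str, Counter]:
    """Run-length histogram of uniform-category motifs, per category.

    A motif is a maximal run of residues with the same category; runs break
    at chain boundaries.  Returns ``{category: Counter({length: n_runs})}``.
    """
    hist: dict[str, Counter] = {}
    run_cat: str | None = None
    run_chain: str | None = None
    run_len = 0

    def close():
        if run_cat is not None:
            hist.setdefault(run_cat, Counter())[run_len] += 1

    for chain, _resnum, cat in labels.records:
        if cat == run_cat and chain == run_chain:
            run_len += 1
        else:
            close()
            run_cat, run_chain, run_len = cat, chain, 1
    close()
    return hist
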