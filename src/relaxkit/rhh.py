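"""Secondary-structure prediction and Ribbon-Helix-Helix (RHH) classification.

The RHH fold (CopG paradigm) is an N-terminal DNA-binding motif: a short
beta-strand followed by two alpha-helices; the antiparallel strands of a
dimer form the ribbon that inserts into the major groove.  Auxiliary
relaxosome proteins of MOB-family conjugation systems characteristically
carry this motif near their N-terminus.

Secondary structure is assigned with a Chou-Fasman-style propensity rule set
(the published single-residue propensity table ships with the package):

* helix nucleation: a 6-residue window with >= 4 helix formers
  (P(helix) >= 1.0) and mean P(helix) > 1.03, extended residue-by-residue in
  both directions while the trailing 4-residue window mean stays >= 1.00;
* strand nucleation: a 5-residue window with >= 3 strand formers
  (P(strand) >= 1.0) and mean P(strand) > 1.05, extended the same way;
* overlaps are resolved per contiguous overlap run by the larger mean
  propensity (ties go to helix); everything else is coil.

This is a deterministic classical predictor, not a machine-learned one; the
RHH geometry thresholds below (strand >= 3 residues, helices >= 6, gap caps
6 and 8, N-terminal window 50) encode CopG-family architecture and are all
configurable.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from .errors import InputError
from ._util import round_half_away


def _load_propensities() -> tuple[dict[str, float], dict[str, float]]:
    p_helix: dict[str, float] = {}
    p_strand: dict[str, float] = {}
    ref = resources.files("relaxkit").joinpath("data/chou_fasman.tsv")
    with ref.open() as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            p_helix[row["residue"]] = float(row["p_helix"])
            p_strand[row["residue"]] = float(row["p_strand"])
    return p_helix, p_strand


P_HELIX, P_STRAND = _load_propensities()
AMINO_ACIDS = "".join(sorted(P_HELIX))


@dataclass(frozen=True)
class SSParams:
    """Rule thresholds for the propensity-based secondary-structure assignment."""

    helix_nuc_window: int = 6
    helix_nuc_formers: int = 4
    helix_nuc_mean: float = 1.03
    strand_nuc_window: int = 5
    strand_nuc_formers: int = 3
    strand_nuc_mean: float = 1.05
    ext_window: int = 4
    ext_mean: float = 1.00


@dataclass(frozen=True)
class RHHParams:
    """Geometry thresholds for the N-terminal RHH signature."""

    window: int = 50        # strand must start within this many N-terminal residues
    min_strand: int = 3
    min_helix: int = 6
    gap1_max: int = 6       # strand -> helix1
    gap2_max: int = 8       # helix1 -> helix2


@dataclass
class SSPrediction:
    """Per-residue secondary structure over {H, E, C}, aligned to the sequence."""

    protein_id: str
    sequence: str
    ss: str

    def __post_init__(self) -> None:
        assert len(self.ss) == len(self.sequence)


@dataclass
class RHHCall:
    """Outcome of the RHH screen for one protein.

    Intervals are 1-based inclusive.  ``basic_junction_count`` counts K/R in
    the region spanning the last three residues of helix 1 through the first
    three of helix 2 (inclusive of the inter-helix gap) — in solved RHH
    structures this face approaches the DNA phosphate backbone.  It is
    reported as supporting evidence, never used as a filter.
    """

    positive: bool
    strand: tuple[int, int] | None = None
    helix1: tuple[int, int] | None = None
    helix2: tuple[int, int] | None = None
    basic_junction_count: int = 0


def _validate(seq: str) -> None:
    bad = set(seq) - set(AMINO_ACIDS)
    if bad:
        raise InputError(f"unknown residue(s): {sorted(bad)}")


def _nucleate_and_extend(p: np.ndarray, window: int, formers: int,
                         nuc_mean: float, params: SSParams) -> list[tuple[int, int]]:
    """Return merged, extended segments [start, end) for one structure class."""
    L = len(p)
    claimed = np.zeros(L, dtype=bool)
    for i in range(L - window + 1):
        win = p[i:i + window]
        if int((win >= 1.0).sum()) >= formers and win.mean() > nuc_mean:
            claimed[i:i + window] = True
    segs = _runs(claimed)
    w = params.ext_window
    extended = []
    for s, e in segs:
        while e < L and p[max(0, e - w + 1):e + 1].mean() >= params.ext_mean:
            e += 1
        while s > 0 and p[s - 1:s - 1 + w].mean() >= params.ext_mean:
            s -= 1
        extended.append((s, e))
    # extension can make segments touch; merge
    merged: list[tuple[int, int]] = []
    for s, e in sorted(extended):
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    runs = []
    s = None
    for i, v in enumerate(mask):
        if v and s is None:
            s = i
        elif not v and s is not None:
            runs.append((s, i))
            s = None
    if s is not None:
        runs.append((s, len(mask)))
    return runs


def predict_ss(protein: str, protein_id: str = "", params: SSParams = SSParams()) -> SSPrediction:
    """Assign H/E/C secondary structure to a protein (length >= 10)."""
    _validate(protein)
    if len(protein) < 10:
        raise InputError("secondary-structure prediction needs >= 10 residues")
    pa = np.array([P_HELIX[r] for r in protein])
    pb = np.array([P_STRAND[r] for r in protein])
    helix = _nucleate_and_extend(pa, params.helix_nuc_window,
                                 params.helix_nuc_formers,
                                 params.helix_nuc_mean, params)
    strand = _nucleate_and_extend(pb, params.strand_nuc_window,
                                  params.strand_nuc_formers,
                                  params.strand_nuc_mean, params)
    is_h = np.zeros(len(protein), dtype=bool)
    is_e = np.zeros(len(protein), dtype=bool)
    for s, e in helix:
        is_h[s:e] = True
    for s, e in strand:
        is_e[s:e] = True
    for s, e in _runs(is_h & is_e):
        if pb[s:e].mean() > pa[s:e].mean():
            is_h[s:e] = False
        else:
            is_e[s:e] = False
    ss = np.full(len(protein), "C", dtype="U1")
    ss[is_h] = "H"
    ss[is_e] = "E"
    return SSPrediction(protein_id, protein, "".join(ss))


def _ss_runs(ss: str) -> list[tuple[str, int, int]]:
    """Maximal runs of the ss string as (state, start0, end0-exclusive)."""
    runs = []
    s = 0
    for i in range(1, len(ss) + 1):
        if i == len(ss) or ss[i] != ss[s]:
            runs.append((ss[s], s, i))
            s = i
    return runs


def detect_rhh(pred: SSPrediction, params: RHHParams = RHHParams()) -> RHHCall:
    """Classify the N-terminal strand–helix–helix signature.

    Positive iff an E-run of >= ``min_strand`` starts within the first
    ``window`` residues, followed (gap <= ``gap1_max``) by an H-run of
    >= ``min_helix``, followed (gap <= ``gap2_max``) by a second such H-run.
    The first qualifying arrangement, scanning from the N-terminus, is
    reported.
    """
    ss, seq = pred.ss, pred.sequence
    window = min(params.window, len(ss))  # clamp for proteins shorter than the window
    runs = _ss_runs(ss)
    e_runs = [(s, e) for st, s, e in runs
              if st == "E" and e - s >= params.min_strand and s < window]
    h_runs = [(s, e) for st, s, e in runs if st == "H" and e - s >= params.min_helix]
    for es, ee in e_runs:
        h1 = next(((s, e) for s, e in h_runs
                   if s >= ee and s - ee <= params.gap1_max), None)
        if h1 is None:
            continue
        h2 = next(((s, e) for s, e in h_runs
                   if s >= h1[1] and s - h1[1] <= params.gap2_max), None)
        if h2 is None:
            continue
        junction = seq[h1[1] - 3:h2[0] + 3]
        kr = sum(1 for r in junction if r in "KR")
        return RHHCall(True, strand=(es + 1, ee), helix1=(h1[0] + 1, h1[1]),
                       helix2=(h2[0] + 1, h2[1]), basic_junction_count=kr)
    return RHHCall(False)


def percent_positive(positives: int, total: int) -> float:
    """Report percentage to one decimal, ties rounded away from zero."""
    if total == 0:
        return 0.0
    return round_half_away(100.0 * positives / total, 1)


def screen_candidates(proteins: dict[str, str],
                      ss_params: SSParams = SSParams(),
                      rhh_params: RHHParams = RHHParams()) -> tuple[float, pd.DataFrame]:
    """RHH-screen a protein set; return (percent positive, per-protein table)."""
    rows = []
    for pid, seq in proteins.items():
        pred = predict_ss(seq, pid, ss_params)
        call = detect_rhh(pred, rhh_params)
        rows.append({
            "protein_id": pid,
            "ss": pred.ss,
            "rhh_positive": call.positive,
            "strand_start": call.strand[0] if call.strand else pd.NA,
            "strand_end": call.strand[1] if call.strand else pd.NA,
            "helix1_start": call.helix1[0] if call.helix1 else pd.NA,
            "helix1_end": call.helix1[1] if call.helix1 else pd.NA,
            "helix2_start": call.helix2[0] if call.helix2 else pd.NA,
            "helix2_end": call.helix2[1] if call.helix2 else pd.NA,
            "basic_junction_count": call.basic_junction_count,
        })
    table = pd.DataFrame(rows)
    pct = percent_positive(int(table["rhh_positive"].sum()) if len(table) else 0,
                           len(table))
    return pct, table
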