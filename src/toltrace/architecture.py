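"""Segment a force transducer into its three domains and quantify the
composition of the periplasm-spanning domain II.

Domain I is the transmembrane helix (TMH).  Domain II starts at the residue
after the TMH and runs to the start of domain III, which is by convention
the final 100 residues of the protein.  Within domain II the fraction of
residues predicted alpha-helical is compared with the fraction that are
proline — proline content being a minimal proxy for polyproline-II helix
content, which three-state secondary-structure predictors do not call.  The
"motor box" is a short predicted beta-strand inside the disordered region
immediately after the TMH, implicated in engaging the stator dimer of the
proton-motive-force motor.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

from .config import RunConfig
from .formats_io import SecondaryStructureProfile

Span = tuple[int, int]  # 1-based inclusive residue interval


class SegmentationError(ValueError):
    """No TMH available; segmentation is impossible without one."""


@dataclass
class TransducerArchitecture:
    gene_id: str
    domain1_span: Optional[Span] = None
    domain2_span: Optional[Span] = None
    domain3_span: Optional[Span] = None
    motor_box_span: Optional[Span] = None
    d2_length: int = 0
    helix_pct: Optional[float] = None
    proline_pct: Optional[float] = None
    ppii_fraction: Optional[float] = None
    lipo_class: str = "none"
    composition_class: Optional[str] = None
    flagged: bool = False
    flag_reason: str = ""


def _span_len(span: Optional[Span]) -> int:
    return 0 if span is None else span[1] - span[0] + 1


def segment_domains(
    profile: SecondaryStructureProfile,
    protein_length: Optional[int] = None,
) -> tuple[Optional[Span], Optional[Span], Optional[Span], bool]:
    """Split [1, L] into domain I (TMH), II (post-TMH) and III (final 100).

    Domain II = [tmh_end+1, L-100]; domain III = [L-99, L].  When the
    protein is too short for a non-empty domain II the record is flagged;
    when the final-100 window would reach into the TMH, domain III is
    clipped to start after it (also flagged).  Returns
    (d1, d2, d3, flagged); empty spans are None.
    """
    if profile.tmh_span is None:
        raise SegmentationError(f"{profile.gene_id}: no TMH predicted")
    length = protein_length if protein_length is not None else len(profile)
    tmh_start, tmh_end = profile.tmh_span
    d1: Span = (tmh_start, tmh_end)
    flagged = False

    d2_start, d2_end = tmh_end + 1, length - 100
    d2: Optional[Span] = (d2_start, d2_end) if d2_start <= d2_end else None
    if d2 is None:
        flagged = True

    d3_start, d3_end = length - 99, length
    if d3_start <= tmh_end:
        d3_start = tmh_end + 1
        flagged = True
    d3: Optional[Span] = (d3_start, d3_end) if d3_start <= d3_end else None
    return d1, d2, d3, flagged


def detect_motor_box(
    profile: SecondaryStructureProfile,
    domain2_span: Span,
    window: int = 75,
    min_strand: int = 3,
    min_coil_flank: int = 3,
) -> Optional[Span]:
    """First qualifying beta-strand run at the start of domain II, or None.

    A qualifying run has >= min_strand consecutive E states, begins within
    the first ``window`` residues of domain II, and is flanked on both sides
    by >= min_coil_flank C states.
    """
    states = profile.states
    d2_start, d2_end = domain2_span
    latest_start = min(d2_end, d2_start + window - 1)
    i = d2_start
    while i <= latest_start:
        if states[i - 1] != "E":
            i += 1
            continue
        run_start = i
        j = i
        while j <= d2_end and states[j - 1] == "E":
            j += 1
        run_end = j - 1
        run_len = run_end - run_start + 1
        if run_len >= min_strand:
            left = states[max(0, run_start - 1 - min_coil_flank):run_start - 1]
            right = states[run_end:run_end + min_coil_flank]
            if (
                len(left) >= min_coil_flank and set(left) == {"C"}
                and len(right) >= min_coil_flank and set(right) == {"C"}
            ):
                return (run_start, run_end)
        i = run_end + 1
    return None


def composition_metrics(
    profile: SecondaryStructureProfile,
    sequence: str,
    domain2_span: Optional[Span],
) -> tuple[Optional[float], Optional[float], int]:
    """(helix_pct, proline_pct, d2_length) over domain II.

    helix_pct counts H states in the SS string; proline_pct counts P
    residues in the amino-acid sequence; both are percentages of the domain
    II length.  Empty domain II leaves the metrics undefined.
    """
    if domain2_span is None:
        return None, None, 0
    s, e = domain2_span
    d2_len = e - s + 1
    n_h = profile.states[s - 1:e].count("H")
    n_p = sequence[s - 1:e].upper().count("P")
    return 100.0 * n_h / d2_len, 100.0 * n_p / d2_len, d2_len


def classify_composition(
    helix_pct: float,
    proline_pct: float,
    ratio: float = 2.0,
    floor: float = 10.0,
) -> str:
    """alpha_dominant / proline_dominant / disordered / mixed.

    A class dominates when its percentage is at least ``ratio`` times the
    other and at least ``floor``; below ``floor`` on both counts the domain
    is called disordered; anything else is mixed.
    """
    if helix_pct >= ratio * proline_pct and helix_pct >= floor:
        return "alpha_dominant"
    if proline_pct >= ratio * helix_pct and proline_pct >= floor:
        return "proline_dominant"
    if helix_pct < floor and proline_pct < floor:
        return "disordered"
    return "mixed"


def ppii_summary(
    ppii_scores: Optional[Sequence[float]],
    domain2_span: Optional[Span],
    cutoff: float = 0.5,
) -> Optional[float]:
    """Fraction of domain II residues with PPII propensity >= cutoff."""
    if ppii_scores is None or domain2_span is None:
        return None
    s, e = domain2_span
    window = ppii_scores[s - 1:e]
    if not window:
        return None
    return sum(1 for x in window if x >= cutoff) / len(window)


_LIPOBOX_RESIDUE_RANGE = (10, 40)  # Cys-terminal motif must lie within these residues
_LIPOBOX_1 = set("LIV")
_LIPOBOX_2 = set("ASTVI")
_LIPOBOX_3 = set("GAS")


def classify_lipoprotein(
    signal_call: Optional[str] = None,
    sequence: Optional[str] = None,
) -> str:
    """Lipidation / secretion class: external call wins; lipobox fallback.

    With no external prediction, a lipobox [LIV][ASTVI][GAS]C whose four
    residues all fall within positions 10-40 marks a lipoprotein.  Without
    either input the class is ``none``.
    """
    if signal_call is not None:
        return signal_call
    if sequence is None:
        return "none"
    seq = sequence.upper()
    lo, hi = _LIPOBOX_RESIDUE_RANGE
    for pos in range(lo, hi - 2):  # pos = 1-based index of the motif start
        window = seq[pos - 1:pos + 3]
        if len(window) < 4:
            break
        if (
            window[0] in _LIPOBOX_1 and window[1] in _LIPOBOX_2
            and window[2] in _LIPOBOX_3 and window[3] == "C"
        ):
            return "lipoprotein"
    return "none"


def analyze_transducer(
    profile: SecondaryStructureProfile,
    sequence: Optional[str] = None,
    config: RunConfig = RunConfig(),
) -> TransducerArchitecture:
    """Full per-protein architecture record.

    A transducer without a predicted TMH is emitted with empty spans and
    flagged (excluded from cohort statistics) rather than guessing a TMH.
    """
    gene_id = profile.gene_id
    if profile.tmh_span is None:
        return TransducerArchitecture(
            gene_id=gene_id, flagged=True, flag_reason="no TMH predicted",
            lipo_class=classify_lipoprotein(profile.signal_call, sequence),
        )
    length = len(profile)
    d1, d2, d3, flagged = segment_domains(profile, length)
    motor_box = None
    helix_pct = proline_pct = None
    d2_len = 0
    ppii = None
    if d2 is not None:
        motor_box = detect_motor_box(
            profile, d2, config.motor_box_window, config.min_strand,
            config.min_coil_flank,
        )
        if sequence is not None:
            helix_pct, proline_pct, d2_len = composition_metrics(
                profile, sequence, d2
            )
        else:
            d2_len = _span_len(d2)
            helix_pct = 100.0 * profile.states[d2[0] - 1:d2[1]].count("H") / d2_len
        ppii = ppii_summary(profile.ppii_scores, d2, config.ppii_cutoff)
    comp_class = None
    if helix_pct is not None and proline_pct is not None:
        comp_class = classify_composition(
            helix_pct, proline_pct, config.comp_ratio, config.comp_floor
        )
    return TransducerArchitecture(
        gene_id=gene_id,
        domain1_span=d1,
        domain2_span=d2,
        domain3_span=d3,
        motor_box_span=motor_box,
        d2_length=d2_len,
        helix_pct=helix_pct,
        proline_pct=proline_pct,
        ppii_fraction=ppii,
        lipo_class=classify_lipoprotein(profile.signal_call, sequence),
        composition_class=comp_class,
        flagged=flagged,
        flag_reason="empty domain II" if flagged and d2 is None else
                    ("domain III clipped at TMH" if flagged else ""),
    )
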