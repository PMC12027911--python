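"""Copy-number arithmetic: probe copies, HL normalization, and bracketing.

All quantification is expressed in HL ("healthy level") units: the copy
number of a miRNA per 1 uL of total-RNA isolate, normalized to a common
total-RNA content of 16.0 ng/uL and divided by the reference copy number
measured in a commercial combined healthy serum.  A threshold test places
a known number of probe copies at a designed HL level (typically 1.5) and
reads the binary detection/silencing outcome as "target below/above the
designed level".  An unknown level is then *bracketed* between the highest
level that silenced and the lowest that detected; brackets spaced ~40%
apart pin the value to roughly +/-20%.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "ReferencePanel",
    "SampleSpec",
    "BracketResult",
    "DEFAULT_PANEL",
    "BracketInconsistencyError",
    "probe_copies",
    "hl_level",
    "hl_level_spec",
    "normalize_copies",
    "fold_hl",
    "design_threshold_test",
    "interpret_threshold_test",
    "bracket_estimate",
]

REFERENCE_RNA_CONC = 16.0  # ng/uL, the common total-RNA content
COPIES_PER_FM_PER_UL = 600.0  # worksheet constant; exact Avogadro is 602.214
AVOGADRO_COPIES_PER_FM_PER_UL = 602.214  # 1 fM = 602.214 copies/uL


class BracketInconsistencyError(ValueError):
    """A silencing outcome sits above a detection outcome; results conflict."""


@dataclass(frozen=True)
class ReferencePanel:
    """Reference miRNA copies per 1 uL of total RNA at 16 ng/uL."""

    copies: dict[str, float]
    reference_rna_conc: float = REFERENCE_RNA_CONC

    def __post_init__(self):
        if any(v <= 0 for v in self.copies.values()):
            raise ValueError("reference copies must be positive")

    def __getitem__(self, mirna: str) -> float:
        try:
            return self.copies[mirna]
        except KeyError:
            raise KeyError(f"miRNA {mirna!r} not in reference panel") from None

    def __contains__(self, mirna: str) -> bool:
        return mirna in self.copies


DEFAULT_PANEL = ReferencePanel(
    copies={"miR-15b": 17710.0, "miR-21": 10494.0, "miR-375": 9240.0, "miR-141": 6096.0}
)


@dataclass(frozen=True)
class SampleSpec:
    """One prepared mixture: probe aliquot + RNA isolate (before buffer)."""

    probe_id: str
    target: str
    probe_conc_fm: float
    probe_volume_ul: float
    sample_volume_ul: float
    rna_conc_ng_ul: float
    copies_per_fm_per_ul: float = COPIES_PER_FM_PER_UL

    def __post_init__(self):
        if self.probe_volume_ul < 0 or self.probe_conc_fm < 0:
            raise ValueError("probe volume and concentration must be >= 0")
        if self.sample_volume_ul <= 0 or self.rna_conc_ng_ul <= 0:
            raise ValueError("sample volume and RNA concentration must be positive")

    @property
    def probe_copies(self) -> float:
        return probe_copies(self.probe_volume_ul, self.probe_conc_fm, self.copies_per_fm_per_ul)


@dataclass(frozen=True)
class BracketResult:
    """An unknown level pinned between a silencing and a detection outcome.

    ``half_spread_fraction`` is (upper-lower)/(upper+lower), the half-spread
    over the midpoint; ``spread_over_lower`` = (upper-lower)/lower is the
    same gap referred to the lower bound (a 40% design gap gives ~16.7% and
    40% respectively).
    """

    lower_HL: float
    upper_HL: float
    midpoint_HL: float
    half_spread_fraction: float
    spread_over_lower: float


def probe_copies(volume_ul: float, conc_fm: float, factor: float = COPIES_PER_FM_PER_UL) -> float:
    """Probe copies in an aliquot: volume (uL) x concentration (fM) x factor."""
    if volume_ul < 0 or conc_fm < 0 or factor < 0:
        raise ValueError("volume, concentration, and factor must be >= 0")
    return volume_ul * conc_fm * factor


def hl_level(
    probe_volume_ul: float,
    probe_conc_fm: float,
    sample_volume_ul: float,
    rna_conc_ng_ul: float,
    reference_copies: float,
    factor: float = COPIES_PER_FM_PER_UL,
    reference_rna_conc: float = REFERENCE_RNA_CONC,
) -> float:
    """Designed probe level in HL units for a prepared mixture.

    Probe copies per 1 uL of mixture, normalized to the reference RNA
    content, divided by the reference copy number:

        HL = (V_probe x C_probe x factor) / V_sample x (16 / C_RNA) / ref
    """
    if sample_volume_ul <= 0 or rna_conc_ng_ul <= 0 or reference_copies <= 0:
        raise ValueError("sample volume, RNA concentration, and reference must be positive")
    per_ul = probe_copies(probe_volume_ul, probe_conc_fm, factor) / sample_volume_ul
    return per_ul * (reference_rna_conc / rna_conc_ng_ul) / reference_copies


def hl_level_spec(spec: SampleSpec, panel: ReferencePanel = DEFAULT_PANEL) -> float:
    """HL level of a :class:`SampleSpec` against a reference panel."""
    if spec.target not in panel:
        raise KeyError(f"target {spec.target!r} not in reference panel")
    return hl_level(
        spec.probe_volume_ul, spec.probe_conc_fm, spec.sample_volume_ul,
        spec.rna_conc_ng_ul, panel[spec.target], spec.copies_per_fm_per_ul,
        panel.reference_rna_conc,
    )


def normalize_copies(measured_copies_per_ul: float, rna_conc_ng_ul: float,
                     reference_rna_conc: float = REFERENCE_RNA_CONC) -> float:
    """Rescale measured copies/uL to the common 16 ng/uL total-RNA content."""
    if rna_conc_ng_ul <= 0:
        raise ValueError("RNA concentration must be positive")
    return measured_copies_per_ul * reference_rna_conc / rna_conc_ng_ul


def fold_hl(normalized_copies: float, target: str, panel: ReferencePanel = DEFAULT_PANEL) -> float:
    """Fold expression over the healthy reference (x HL)."""
    return normalized_copies / panel[target]


def design_threshold_test(
    target: str,
    rna_conc_ng_ul: float,
    probe_conc_fm: float,
    sample_volume_ul: float,
    desired_hl: float = 1.5,
    panel: ReferencePanel = DEFAULT_PANEL,
    factor: float = COPIES_PER_FM_PER_UL,
) -> float:
    """Probe volume (uL) that puts the probe at ``desired_hl``; inverts
    :func:`hl_level`."""
    if desired_hl < 0:
        raise ValueError("desired HL must be >= 0")
    if probe_conc_fm <= 0 or factor <= 0:
        raise ValueError("infeasible design: probe concentration must be positive")
    if rna_conc_ng_ul <= 0 or sample_volume_ul <= 0:
        raise ValueError("RNA concentration and sample volume must be positive")
    ref = panel[target]
    return (
        desired_hl * ref * sample_volume_ul * rna_conc_ng_ul
        / (panel.reference_rna_conc * probe_conc_fm * factor)
    )


def interpret_threshold_test(call: str, designed_hl: float) -> str:
    """Read a binary outcome as the target's side of the designed level.

    Detection means free probe was present, so the target falls short of
    the probe: target < designed level.  Silencing means the probe was
    fully hybridized: target > designed level.
    """
    if call == "detection":
        return "below"
    if call == "silencing":
        return "above"
    raise ValueError(f"no interpretation for call {call!r} (rejected tests carry no information)")


def bracket_estimate(results: list[tuple[float, str]]) -> BracketResult:
    """Bracket an unknown level from a ladder of threshold-test outcomes.

    ``results`` pairs each designed HL level with its call.  The unknown
    lies above every silencing level and below every detection level;
    the bracket is (max silencing, min detection).
    """
    silencing = [hl for hl, call in results if call == "silencing"]
    detection = [hl for hl, call in results if call == "detection"]
    if not silencing or not detection:
        raise ValueError("need at least one silencing and one detection outcome")
    lower, upper = max(silencing), min(detection)
    if lower >= upper:
        raise BracketInconsistencyError(
            f"silencing at {lower} HL contradicts detection at {upper} HL"
        )
    midpoint = (lower + upper) / 2.0
    return BracketResult(
        lower_HL=lower,
        upper_HL=upper,
        midpoint_HL=midpoint,
        half_spread_fraction=(upper - lower) / (upper + lower),
        spread_over_lower=(upper - lower) / lower,
    )
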