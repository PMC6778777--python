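"""PCR-panel validation logic and the ZW-vs-XY decision rule.

ZW and XY sex determination are mutually exclusive, so a panel of candidate
markers screened by PCR in known-sex individuals must resolve the system:
if at least one marker amplifies only in females and none only in males,
the species is female-heterogametic (ZW); the mirrored pattern gives XY.
Candidates from the wrong hypothesis co-amplify in both sexes.

Every reaction is interpreted alongside an autosomal positive-control
marker (an 18S rRNA assay): individuals whose control fails are excluded
from marker classification rather than scored as non-amplifying, because a
failed reaction is indistinguishable from a true absence.

The same logic powers the production sex assay under a ZW verdict:
amplification of any W-linked marker (with a working control) calls a
female; no amplification calls a male, with the caveat that a primer-site
mutation would mimic maleness — hence multiple W markers plus the control.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

CONTROL_MARKER = "18S"

FEMALE_SPECIFIC = "female_specific"
MALE_SPECIFIC = "male_specific"
CO_AMPLIFYING = "co_amplifying"
FAILED = "failed"

# BatchPrimer3 settings used for marker primer design, recorded for
# documentation export only (primer design itself is out of scope).
PRIMER_DESIGN_SETTINGS = {
    "primer_length_bp": {"min": 23, "opt": 30, "max": 33},
    "max_tm_difference_c": 5,
    "amplicon_length_bp": {"min": 375, "opt": 500, "max": 550},
    "positive_control": {"marker": CONTROL_MARKER, "amplicon_bp": 756},
}


@dataclass
class PanelResult:
    """Amplification outcomes for a marker x individual PCR panel.

    ``amplified`` is a boolean DataFrame indexed by marker (including the
    positive-control row) with one column per individual; ``sexes`` holds
    the recorded (claimed) sex of each individual.
    """

    amplified: pd.DataFrame
    sexes: dict[str, str]

    def __post_init__(self) -> None:
        if CONTROL_MARKER not in self.amplified.index:
            raise ValueError(f"panel must include the positive-control marker {CONTROL_MARKER!r}")
        missing = set(self.amplified.columns) - set(self.sexes)
        if missing:
            raise ValueError(f"individuals without a sex label: {sorted(missing)}")

    @property
    def control_ok(self) -> pd.Series:
        return self.amplified.loc[CONTROL_MARKER]

    @property
    def markers(self) -> list:
        return [m for m in self.amplified.index if m != CONTROL_MARKER]


def classify_marker(
    amplified: Mapping[str, bool],
    sexes: Mapping[str, str],
    control_ok: Mapping[str, bool],
) -> str:
    """Classify one marker's amplification column.

    Individuals with a failed positive control are excluded from the
    evaluation.  Over the evaluable individuals: female_specific iff it
    amplified in every female and no male; male_specific mirrored;
    co_amplifying iff it amplified in at least one of each sex; failed iff
    it amplified in none.  A marker amplifying in only part of one sex (and
    none of the other) is also reported as failed: it is unusable as a
    sex-diagnostic marker.
    """
    evaluable = [i for i in amplified if control_ok.get(i, False)]
    if not evaluable:
        raise ValueError("no individual has a working positive control")
    f = [amplified[i] for i in evaluable if sexes[i] == "female"]
    m = [amplified[i] for i in evaluable if sexes[i] == "male"]
    if f and m:
        if all(f) and not any(m):
            return FEMALE_SPECIFIC
        if all(m) and not any(f):
            return MALE_SPECIFIC
    if any(f) and any(m):
        return CO_AMPLIFYING
    return FAILED


def classify_panel(panel: PanelResult) -> dict:
    """Classify every non-control marker in a panel."""
    control = panel.control_ok.to_dict()
    return {
        marker: classify_marker(panel.amplified.loc[marker].to_dict(), panel.sexes, control)
        for marker in panel.markers
    }


@dataclass
class SystemCall:
    """The heterogamety verdict with its supporting evidence."""

    verdict: str  # ZW | XY | inconclusive | conflict
    supporting_marker_ids: tuple
    classifications: dict = field(default_factory=dict)


def infer_system(classifications: Mapping) -> SystemCall:
    """Mutually-exclusive decision rule over classified markers.

    ZW requires at least one female-specific marker and zero male-specific
    markers (XY mirrored); no sex-specific marker at all is inconclusive;
    sex-specific markers in both directions flag a conflict (sample
    mislabelling or a non-standard system).
    """
    if not classifications:
        raise ValueError("at least one classified marker is required")
    f = tuple(m for m, c in classifications.items() if c == FEMALE_SPECIFIC)
    m = tuple(m for m, c in classifications.items() if c == MALE_SPECIFIC)
    if f and not m:
        verdict, support = "ZW", f
    elif m and not f:
        verdict, support = "XY", m
    elif f and m:
        verdict, support = "conflict", f + m
    else:
        verdict, support = "inconclusive", ()
    return SystemCall(verdict, support, dict(classifications))


@dataclass(frozen=True)
class SexDiagnosis:
    call: str           # female | male | indeterminate
    discordant: bool    # W markers disagreed (some amplified, some not)
    note: str = ""


def diagnose_sex(w_marker_amplified: Mapping[str, bool], control_ok: bool) -> SexDiagnosis:
    """Production sex assay under a ZW verdict: W markers + positive control.

    A failed control is indeterminate (the reactions cannot be trusted).
    With a working control, any amplifying W marker calls a female; none
    calls a male — with the caveat that a mutation in a primer binding site
    (or general PCR failure of the marker) would masquerade as maleness,
    which is why multiple W markers are assayed.  Discordant marker pairs
    (some amplify, some do not) still call female but are flagged.
    """
    if not w_marker_amplified:
        raise ValueError("at least one W-linked marker must be assayed")
    if not control_ok:
        return SexDiagnosis("indeterminate", False, "positive control failed")
    amplified = list(w_marker_amplified.values())
    if any(amplified):
        discordant = not all(amplified)
        note = "W markers discordant; retest advised" if discordant else ""
        return SexDiagnosis("female", discordant, note)
    return SexDiagnosis(
        "male", False,
        "no W amplification; primer-site mutation or marker failure would mimic maleness",
    )


def simulate_panel(
    marker_truth: Mapping[str, str],
    individuals: Sequence[tuple[str, str]],
    dropout_rate: float = 0.0,
    mislabel_rate: float = 0.0,
    rng: np.random.Generator | None = None,
) -> PanelResult:
    """Simulate a PCR panel from marker ground truth.

    ``marker_truth`` maps marker id -> one of female_specific,
    male_specific, or autosomal (amplifies in everyone); the 18S control row
    is always added.  Each reaction independently drops out (amplification
    suppressed) with ``dropout_rate``; each individual's *recorded* sex is
    flipped with ``mislabel_rate`` while amplification still follows the
    true sex.
    """
    if not 0 <= dropout_rate <= 1 or not 0 <= mislabel_rate <= 1:
        raise ValueError("rates must lie in [0, 1]")
    rng = rng or np.random.default_rng()
    ids = [i for i, _ in individuals]
    true_sex = {i: s for i, s in individuals}
    recorded = {
        i: (("male" if s == "female" else "female") if rng.random() < mislabel_rate else s)
        for i, s in individuals
    }
    markers = list(marker_truth) + [CONTROL_MARKER]
    amplified = pd.DataFrame(False, index=markers, columns=ids)
    for marker in markers:
        truth = marker_truth.get(marker, "autosomal")
        for i in ids:
            works = (
                truth == "autosomal"
                or marker == CONTROL_MARKER
                or (truth == FEMALE_SPECIFIC and true_sex[i] == "female")
                or (truth == MALE_SPECIFIC and true_sex[i] == "male")
            )
            if works and rng.random() >= dropout_rate:
                amplified.loc[marker, i] = True
    return PanelResult(amplified=amplified, sexes=recorded)


def panel_report(panel: PanelResult) -> pd.DataFrame:
    """Per-marker classification table for export."""
    classifications = classify_panel(panel)
    evaluable = int(panel.control_ok.sum())
    return pd.DataFrame(
        {
            "marker": list(classifications),
            "classification": list(classifications.values()),
            "n_evaluable": evaluable,
        }
    )
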