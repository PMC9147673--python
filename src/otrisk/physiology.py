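"""Reference adult physiology for the whole-body PBPK model.

The compound-specific parameters of the o-toluidine model are published
(see :mod:`otrisk.pbpk`); the anatomy and physiology are not, so this file
fixes a self-consistent standard reference adult (70 kg, cardiac output
390 L/h = 6.5 L/min) assembled from ICRP-style reference tables.  Every
number below is a deliberate constant of this package; changing any of them
changes model output, so they are versioned here rather than scattered
through the code.

Tissue volumes are perfused-tissue volumes in litres; blood flows are given
as fractions of cardiac output and sum to exactly 1 (the muscle fraction is
the balancing term).  The "lung" flow is the bronchial fraction only — the
model lumps arterial and venous blood into a single pool, so pulmonary
(total cardiac output) flow is implicit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import ValidationError

PHYSIOLOGY_VERSION = "reference-adult-1"

TISSUES = ("GI", "liver", "kidney", "fat", "bone", "brain",
           "gonads", "heart", "muscle", "skin", "lung")

#: perfused tissue volumes (L) for a 70-kg reference adult
REFERENCE_TISSUE_VOLUMES = {
    "GI": 1.2,
    "liver": 1.8,
    "kidney": 0.31,
    "fat": 14.5,
    "bone": 5.0,
    "brain": 1.45,
    "gonads": 0.035,
    "heart": 0.33,
    "muscle": 28.0,
    "skin": 2.6,
    "lung": 0.5,
}

REFERENCE_BLOOD_VOLUME = 5.3  # L

#: fractions of cardiac output; "liver" is the hepatic-artery fraction only,
#: the portal (GI) fraction reaches the liver in series.
REFERENCE_FLOW_FRACTIONS = {
    "GI": 0.185,
    "liver": 0.07,
    "kidney": 0.19,
    "fat": 0.05,
    "bone": 0.05,
    "brain": 0.12,
    "gonads": 0.0005,
    "heart": 0.04,
    "muscle": 0.2115,
    "skin": 0.058,
    "lung": 0.025,
}

REFERENCE_BW = 70.0  # kg
REFERENCE_CARDIAC_OUTPUT = 390.0  # L/h
REFERENCE_VENTILATION = 1.25  # m3/h at light work: 10 m3 over an 8-h shift
REFERENCE_URINE_FLOW = 1.5 / 24.0  # L/h: the 1.5 L/day 24-h urine volume


@dataclass(frozen=True)
class Physiology:
    """Anatomical/physiological parameter set of the PBPK model.

    Defaults describe the reference 70-kg adult.  ``scaled`` produces a
    body-size variant: volumes, blood volume and urine flow scale linearly
    with body weight, perfusion allometrically (exponent 0.75).
    """

    bw: float = REFERENCE_BW
    cardiac_output: float = REFERENCE_CARDIAC_OUTPUT
    tissue_volumes: dict[str, float] = field(
        default_factory=lambda: dict(REFERENCE_TISSUE_VOLUMES))
    tissue_blood_flows: dict[str, float] = field(
        default_factory=lambda: {t: f * REFERENCE_CARDIAC_OUTPUT
                                 for t, f in REFERENCE_FLOW_FRACTIONS.items()})
    blood_volume: float = REFERENCE_BLOOD_VOLUME
    ventilation_rate: float = REFERENCE_VENTILATION
    urine_flow: float = REFERENCE_URINE_FLOW

    def __post_init__(self) -> None:
        missing = set(TISSUES) - set(self.tissue_volumes)
        if missing or set(TISSUES) - set(self.tissue_blood_flows):
            raise ValidationError(f"tissue maps must cover {TISSUES}")
        if any(v <= 0 for v in self.tissue_volumes.values()):
            raise ValidationError("tissue volumes must be positive")
        if any(q <= 0 for q in self.tissue_blood_flows.values()):
            raise ValidationError("tissue blood flows must be positive")
        total_volume = sum(self.tissue_volumes.values()) + self.blood_volume
        if total_volume >= self.bw:  # 1 kg ~ 1 L; the remainder is unperfused content
            raise ValidationError(
                f"perfused volume {total_volume:.1f} L must be below body weight {self.bw} kg")
        total_flow = sum(self.tissue_blood_flows.values())
        if abs(total_flow - self.cardiac_output) > 0.01 * self.cardiac_output:
            raise ValidationError(
                f"tissue blood flows sum to {total_flow:.1f} L/h, "
                f"not within 1% of cardiac output {self.cardiac_output} L/h")
        for name in ("bw", "cardiac_output", "blood_volume", "ventilation_rate", "urine_flow"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")

    def scaled(self, bw_multiplier: float) -> "Physiology":
        """Body-size variant: volumes ~ bw, flows ~ bw^0.75.

        Ventilation and urine flow stay fixed: the inhaled working-day
        volume and the 24-h urine volume are treated as population
        constants throughout the framework (urine output scales only
        weakly with adult body size).
        """
        if bw_multiplier <= 0:
            raise ValidationError("bw_multiplier must be positive")
        m, mq = bw_multiplier, bw_multiplier ** 0.75
        return Physiology(
            bw=self.bw * m,
            cardiac_output=self.cardiac_output * mq,
            tissue_volumes={t: v * m for t, v in self.tissue_volumes.items()},
            tissue_blood_flows={t: q * mq for t, q in self.tissue_blood_flows.items()},
            blood_volume=self.blood_volume * m,
            ventilation_rate=self.ventilation_rate,
            urine_flow=self.urine_flow,
        )
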