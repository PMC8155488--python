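"""Condition registry: genotype x rhythm x drug/dose -> conductance scales.

A *condition* is the full electrophysiological parameterization of one
simulated case: the genotype (wild-type or heterozygous PITX2 deficiency),
the rhythm state (sinus rhythm, or the ion-channel remodeling of persistent
AF), and optionally an antiarrhythmic drug at one of two labeled doses.
Each condition resolves to a single multiplier vector applied to the
maximal conductances / pump rates of the atrial cell model
(:mod:`afvtrial.cellmodel`).

The genotype/rhythm columns are stored verbatim as data (percent of the
unscaled model value).  The "same percent change" rule that links the
sinus-rhythm and AF columns of each genotype is implemented as a
*validation* (:func:`consistency_report`), not as a derivation, because the
published PITX2 AF gK1 entry (158%) differs from exact proportional
derivation (~157%) by a rounding step.

Drug effects are multiplicative block factors on a fixed per-drug channel
subset.  The published source for the per-drug percent blocks is a
supplement that is not distributed with the main text; the factors shipped
here are editable defaults assembled from the experimental literature the
drugs' channel lists cite, constrained to be dose-monotone.  Every resolved
scale vector is recorded per case, so a user can swap in their own table
without touching code.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Mapping

import yaml

from .cellmodel import SCALE_NAMES, ConductanceScales

__all__ = [
    "GENOTYPES",
    "RHYTHMS",
    "DRUGS",
    "DOSES",
    "DRUG_CLASS",
    "DOSE_LABELS",
    "DRUG_CHANNELS",
    "Condition",
    "DrugBlockTable",
    "genotype_baseline",
    "percent_change",
    "apply_drug",
    "consistency_report",
    "default_drug_table",
    "resolve_condition",
    "load_drug_table",
    "dump_drug_table",
]

GENOTYPES = ("wild_type", "pitx2_deficient")
RHYTHMS = ("SR", "AF")
DRUGS = ("none", "amiodarone", "sotalol", "dronedarone", "flecainide", "propafenone")
DOSES = ("low", "high")

#: Pharmacological class of each drug: IC = sodium-channel blockers,
#: III = potassium-channel blockers (amiodarone/dronedarone are in practice
#: multichannel, but are grouped as class III).
DRUG_CLASS = {
    "flecainide": "IC",
    "propafenone": "IC",
    "amiodarone": "III",
    "sotalol": "III",
    "dronedarone": "III",
}

#: Human-readable concentration labels for the two dose levels, kept
#: verbatim from the source literature (including sotalol "10 mM").
DOSE_LABELS = {
    "amiodarone": {"low": "5 uM", "high": "10 uM"},
    "sotalol": {"low": "60 uM", "high": "10 mM"},
    "dronedarone": {"low": "3 uM", "high": "10 uM"},
    "flecainide": {"low": "5 uM", "high": "15 uM"},
    "propafenone": {"low": "5 uM", "high": "10 uM"},
}

#: The channel subset each drug is allowed to touch.
DRUG_CHANNELS = {
    "amiodarone": ("gK1", "gKur", "gNa", "gKr", "gCaL", "gKs", "ACh"),
    "sotalol": ("gNa", "gKr", "gKs"),
    "dronedarone": ("gCaL", "gKs", "gNa", "gK1", "gKr"),
    "flecainide": ("gNa", "gKur", "gto", "gCaL"),
    "propafenone": ("gNa", "gto", "gCaL", "gKur", "gKr"),
}

# Genotype/rhythm baseline columns, percent of the unscaled cell model
# (100 = unchanged).  Stored verbatim; see consistency_report.
_BASELINE_PERCENT = {
    ("wild_type", "SR"): {
        "gNa": 111, "gK1": 95, "gto": 117, "gKr": 120, "gCaL": 150,
        "gKur": 100, "gKs": 160, "INaCa_max": 155, "INaK_max": 100,
        "Iup_max": 100, "Krel": 100, "Caup_max": 125, "ACh": 100,
    },
    ("wild_type", "AF"): {
        "gNa": 90, "gK1": 210, "gto": 30, "gKr": 100, "gCaL": 30,
        "gKur": 50, "gKs": 100, "INaCa_max": 100, "INaK_max": 100,
        "Iup_max": 100, "Krel": 100, "Caup_max": 80, "ACh": 100,
    },
    ("pitx2_deficient", "SR"): {
        "gNa": 111, "gK1": 71, "gto": 117, "gKr": 240, "gCaL": 150,
        "gKur": 100, "gKs": 160, "INaCa_max": 155, "INaK_max": 100,
        "Iup_max": 100, "Krel": 100, "Caup_max": 125, "ACh": 100,
    },
    ("pitx2_deficient", "AF"): {
        "gNa": 90, "gK1": 158, "gto": 30, "gKr": 200, "gCaL": 30,
        "gKur": 50, "gKs": 100, "INaCa_max": 100, "INaK_max": 100,
        "Iup_max": 100, "Krel": 100, "Caup_max": 80, "ACh": 100,
    },
}

# Default multiplicative block factors (fraction of conductance REMAINING)
# per drug and dose.  Editable defaults, not verbatim from the source
# supplement: values assembled from the patch-clamp literature backing each
# drug's channel list, rounded to 0.05, dose-monotone by construction.
_DEFAULT_BLOCKS: dict[str, dict[str, dict[str, float]]] = {
    "amiodarone": {
        # multichannel blocker: INa, IKr, ICaL, IKur, IK1, IKs, IKACh
        "low":  {"gNa": 0.85, "gKr": 0.70, "gCaL": 0.80, "gKur": 0.85,
                 "gK1": 0.90, "gKs": 0.80, "ACh": 0.85},
        "high": {"gNa": 0.70, "gKr": 0.50, "gCaL": 0.65, "gKur": 0.70,
                 "gK1": 0.80, "gKs": 0.60, "ACh": 0.70},
    },
    "sotalol": {
        # predominantly IKr block with weak INa / IKs effects
        "low":  {"gNa": 0.95, "gKr": 0.60, "gKs": 0.95},
        "high": {"gNa": 0.90, "gKr": 0.30, "gKs": 0.85},
    },
    "dronedarone": {
        "low":  {"gCaL": 0.80, "gKs": 0.85, "gNa": 0.90, "gK1": 0.90, "gKr": 0.65},
        "high": {"gCaL": 0.60, "gKs": 0.70, "gNa": 0.75, "gK1": 0.80, "gKr": 0.45},
    },
    "flecainide": {
        # class IC: dominant INa block, secondary Ito/IKur/ICaL; remaining
        # fractions follow atrial IC50 estimates at the two labeled doses
        "low":  {"gNa": 0.75, "gKur": 0.85, "gto": 0.85, "gCaL": 0.95},
        "high": {"gNa": 0.55, "gKur": 0.70, "gto": 0.70, "gCaL": 0.85},
    },
    "propafenone": {
        "low":  {"gNa": 0.75, "gto": 0.85, "gCaL": 0.90, "gKur": 0.85, "gKr": 0.80},
        "high": {"gNa": 0.55, "gto": 0.70, "gCaL": 0.80, "gKur": 0.70, "gKr": 0.65},
    },
}


@dataclass(frozen=True)
class Condition:
    """One point of the trial grid: genotype x rhythm x drug x dose."""

    genotype: str = "wild_type"
    rhythm: str = "SR"
    drug: str = "none"
    dose: str | None = None

    def __post_init__(self) -> None:
        if self.genotype not in GENOTYPES:
            raise ValueError(f"unknown genotype {self.genotype!r}")
        if self.rhythm not in RHYTHMS:
            raise ValueError(f"unknown rhythm {self.rhythm!r}")
        if self.drug not in DRUGS:
            raise ValueError(f"unknown drug {self.drug!r}")
        if self.drug == "none":
            if self.dose is not None:
                raise ValueError("dose given without a drug")
        elif self.dose not in DOSES:
            raise ValueError(f"drug {self.drug!r} needs dose in {DOSES}")

    @property
    def drug_class(self) -> str | None:
        return DRUG_CLASS.get(self.drug)

    @property
    def label(self) -> str:
        if self.drug == "none":
            return f"{self.genotype}/{self.rhythm}/baseline"
        return f"{self.genotype}/{self.rhythm}/{self.drug}:{self.dose}"


@dataclass
class DrugBlockTable:
    """Per drug x dose multiplicative block factors on a channel subset.

    ``blocks[drug][dose][channel]`` is the fraction of the channel's
    conductance remaining under the drug (1.0 = no block).  Validation
    enforces the per-drug channel lists, factors in [0, 1], and that the
    high dose blocks every listed channel at least as strongly as the low
    dose.
    """

    blocks: dict[str, dict[str, dict[str, float]]] = field(default_factory=dict)

    def validate(self) -> None:
        for drug, doses in self.blocks.items():
            if drug not in DRUG_CHANNELS:
                raise ValueError(f"unknown drug {drug!r} in block table")
            allowed = set(DRUG_CHANNELS[drug])
            for dose, factors in doses.items():
                if dose not in DOSES:
                    raise ValueError(f"unknown dose {dose!r} for {drug}")
                extra = set(factors) - allowed
                if extra:
                    raise ValueError(
                        f"{drug} touches channels outside its set: {sorted(extra)}"
                    )
                for ch, f in factors.items():
                    if not (0.0 <= f <= 1.0):
                        raise ValueError(f"{drug}/{dose}/{ch}: factor {f} not in [0,1]")
            if "low" in doses and "high" in doses:
                for ch in doses["high"]:
                    lo = doses["low"].get(ch, 1.0)
                    if doses["high"][ch] > lo + 1e-12:
                        raise ValueError(
                            f"{drug}/{ch}: high-dose factor {doses['high'][ch]} "
                            f"weaker than low-dose {lo}"
                        )

    def factors(self, drug: str, dose: str) -> Mapping[str, float]:
        try:
            return self.blocks[drug][dose]
        except KeyError as e:
            raise KeyError(f"no block entry for {drug}/{dose}") from e


def default_drug_table() -> DrugBlockTable:
    """The shipped (editable-default) drug block table, validated."""
    table = DrugBlockTable({d: {k: dict(v) for k, v in ds.items()}
                            for d, ds in _DEFAULT_BLOCKS.items()})
    table.validate()
    return table


def genotype_baseline(genotype: str, rhythm: str) -> ConductanceScales:
    """Baseline conductance multipliers for a genotype/rhythm combination.

    Returns the stored column as fractions of the unscaled model value
    (1.0 = 100%).
    """
    try:
        col = _BASELINE_PERCENT[(genotype, rhythm)]
    except KeyError:
        raise ValueError(f"unknown genotype/rhythm ({genotype!r}, {rhythm!r})") from None
    return ConductanceScales(**{k: v / 100.0 for k, v in col.items()})


def percent_change(sr_value: float, af_value: float) -> int:
    """Signed percent change SR -> AF, rounded half away from zero.

    Both inputs are in the same (percent-of-baseline) units; the result is
    an integer percentage of the SR value.
    """
    if not (sr_value > 0):
        raise ValueError("sinus-rhythm value must be positive")
    raw = 100.0 * (af_value - sr_value) / sr_value
    return int(math.floor(abs(raw) + 0.5) * (1 if raw >= 0 else -1))


def apply_drug(
    base: ConductanceScales,
    drug: str,
    dose: str | None = None,
    table: DrugBlockTable | None = None,
) -> ConductanceScales:
    """Multiply the drug's block factors into a baseline scale vector.

    Only the channels in the drug's registered subset are touched;
    ``drug="none"`` returns the base unchanged.
    """
    if drug == "none":
        return base
    if drug not in DRUG_CHANNELS:
        raise ValueError(f"unknown drug {drug!r}")
    if dose not in DOSES:
        raise ValueError(f"dose must be one of {DOSES}, got {dose!r}")
    if table is None:
        table = default_drug_table()
    table.validate()
    factors = table.factors(drug, dose)
    values = base.as_dict()
    for ch, f in factors.items():
        values[ch] = values[ch] * f
    return ConductanceScales(**values)


def resolve_condition(
    cond: Condition, table: DrugBlockTable | None = None
) -> ConductanceScales:
    """Full resolution: genotype/rhythm baseline with the drug applied."""
    base = genotype_baseline(cond.genotype, cond.rhythm)
    return apply_drug(base, cond.drug, cond.dose, table)


def consistency_report(
    baseline_percent: Mapping[tuple[str, str], Mapping[str, float]] | None = None,
) -> dict[str, dict[str, float]]:
    """Check the stored PITX2 AF column against the proportionality rule.

    The AF remodeling of the deficient genotype is documented as applying
    the *same percent change* per channel as wild-type SR -> AF.  This
    recomputes the deficient AF column from that rule and reports, per
    channel, the stored value, the derived value and their absolute
    deviation (all as fractions of the unscaled model).
    """
    cols = baseline_percent if baseline_percent is not None else _BASELINE_PERCENT
    wt_sr = cols[("wild_type", "SR")]
    wt_af = cols[("wild_type", "AF")]
    px_sr = cols[("pitx2_deficient", "SR")]
    px_af = cols[("pitx2_deficient", "AF")]
    report: dict[str, dict[str, float]] = {}
    for ch in SCALE_NAMES:
        derived = px_sr[ch] / 100.0 * (wt_af[ch] / wt_sr[ch])
        stored = px_af[ch] / 100.0
        report[ch] = {
            "stored": stored,
            "derived": derived,
            "deviation": abs(stored - derived),
        }
    return report


def dump_drug_table(table: DrugBlockTable) -> str:
    """Serialize a block table to YAML (one block per drug/dose)."""
    return yaml.safe_dump({"drug_blocks": table.blocks}, sort_keys=True)


def load_drug_table(text: str) -> DrugBlockTable:
    """Parse and validate a YAML drug block table."""
    data = yaml.safe_load(text)
    table = DrugBlockTable(data["drug_blocks"])
    table.validate()
    return table


def all_conditions(rhythm: str = "AF") -> list[Condition]:
    """The full drug/dose grid (baseline + 5 drugs x 2 doses) per genotype."""
    out = []
    for g in GENOTYPES:
        out.append(Condition(g, rhythm))
        for d in DRUGS[1:]:
            for dose in DOSES:
                out.append(Condition(g, rhythm, d, dose))
    return out
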