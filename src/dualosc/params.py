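"""Domain types: circuit layout, kinetic parameters and inducer conditions.

Units are molecules per cell and minutes throughout; inducers keep their
experimental units (arabinose in % w/v, IPTG in mM).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field, fields
from pathlib import Path

import yaml

REPORTER_KINDS = ("none", "lac_ara", "lac", "lac_decoy")


@dataclass(frozen=True)
class CircuitConfig:
    """Which reporter variant is attached and which competition channels act.

    The upstream oscillator is fixed: an activator plasmid carrying the
    lac/ara-driven ``araC`` gene (and, when present, the reporter gene) and a
    repressor plasmid carrying the lac/ara-driven ``lacI`` gene.

    Parameters
    ----------
    reporter_kind
        ``"none"`` (bare oscillator), ``"lac_ara"`` (reporter behind the
        hybrid AraC-activated/LacI-repressed promoter), ``"lac"`` (reporter
        behind a two-operator LacI-repressed promoter) or ``"lac_decoy"``
        (lac reporter plus a transcription-free AraC decoy site, equalising
        the total binding-site census with the lac/ara reporter).
    retroactivity_on
        When ``False``, downstream (reporter and decoy) binding sites still
        track their occupancy but no longer sequester the free regulatory
        protein pools ("sense but do not consume").
    protease_sharing_on
        When ``False``, GFP is degraded by an independent protease channel
        with identical kinetics instead of competing with AraC and LacI.
    n_activator_dna, n_repressor_dna
        Plasmid copy numbers per cell.  The reporter gene rides on the
        activator plasmid.
    """

    reporter_kind: str = "lac_ara"
    retroactivity_on: bool = True
    protease_sharing_on: bool = True
    n_activator_dna: int = 50
    n_repressor_dna: int = 25

    def __post_init__(self) -> None:
        if self.reporter_kind not in REPORTER_KINDS:
            raise ValueError(
                f"unknown reporter_kind {self.reporter_kind!r}; "
                f"expected one of {REPORTER_KINDS}"
            )
        for name in ("n_activator_dna", "n_repressor_dna"):
            v = getattr(self, name)
            if not (isinstance(v, (int,)) and v > 0):
                raise ValueError(f"{name} must be a positive integer, got {v!r}")


@dataclass(frozen=True)
class InducerCondition:
    """Inducer concentrations: arabinose in % w/v, IPTG in mM."""

    arabinose: float
    iptg: float

    def __post_init__(self) -> None:
        if self.arabinose < 0 or self.iptg < 0:
            raise ValueError(
                f"inducer concentrations must be nonnegative, got "
                f"arabinose={self.arabinose}, iptg={self.iptg}"
            )


@dataclass(frozen=True)
class ParameterSet:
    """Kinetic constants of the oscillator model (molecules/cell, minutes).

    Promoter occupancy kinetics
    ---------------------------
    ka_on, ka_off
        AraC-dimer association (per free dimer per minute) and dissociation
        at the single AraC half-site of a lac/ara promoter or decoy.  The
        effective on-rate is further multiplied by the arabinose/IPTG
        response (see :func:`dualosc.odes.active_fractions`).
    kr_on, kr_off
        LacI-tetramer association/dissociation at a single lac operator.
    k_loop, k_unloop, k_loop_diss
        DNA-loop kinetics: a singly bound tetramer bridges the second
        operator at ``k_loop`` (per min), the loop opens back to a singly
        bound state at ``k_unloop``, and the looped complex falls off DNA
        entirely at ``k_loop_diss``, releasing the tetramer.

    Transcription / translation
    ---------------------------
    k_tx_active
        Activated transcription rate of the regulatory lac/ara promoter
        (mRNA per promoter copy per min; AraC bound, no LacI).
    k_tx_basal
        Basal rate of an AraC-dependent promoter with AraC absent and no
        repressor bound.
    b_d1
        Maximum transcription rate of the lac/ara *reporter* promoter
        (the quantity written as alpha*b_d1 in the robustness scan).
    b_d2
        Maximum transcription rate of the lac reporter promoter.  The lac
        promoter needs no activator, so this rate applies whenever no LacI
        is bound; by default ``b_d2 == b_d1``.
    k_tl
        Translation rate (protein monomers per mRNA per min).  Functional
        units are produced at ``k_tl / 2`` (AraC dimer), ``k_tl / 4``
        (LacI tetramer) and ``k_tl`` (GFP monomer): multimer assembly is
        treated as fast.
    gamma_m
        First-order mRNA decay rate (per min).

    Degradation / growth
    --------------------
    v_max, k_m
        ClpXP protease: maximum velocity (molecules/min/cell) and Michaelis
        constant (molecules/cell) of SsrA-tagged protein degradation; all
        tagged species share one saturable pool when protease sharing is on.
    dilution
        Growth dilution rate applied to proteins and mRNA (per min).

    Inducer response
    ----------------
    ara_k_half, ara_hill, ara_basal
        Arabinose activation of AraC DNA binding: Hill half-saturation
        (% w/v), Hill exponent and the activity floor at zero arabinose.
    iptg_laci_k_half, iptg_laci_hill
        IPTG inactivation of LacI: Hill half-saturation (mM) and exponent.
    iptg_ara_k_inhib
        IPTG inhibition of arabinose-bound AraC (mM); larger means weaker.
        The inhibition multiplies only the arabinose-dependent part of the
        AraC response, so the basal floor is IPTG-independent.
    arac_assembly_k, laci_assembly_k
        Fast multimer-assembly equilibrium (molecules/cell).  The
        DNA-binding-competent pool is ``x^2 / (x + K)`` of the active pool
        ``x``: quadratic when the active pool is far below ``K`` (few
        complexes assemble) and approaching ``x`` far above it.  ``K = 0``
        means the pool is fully assembled (no cooperativity).
    """

    ka_on: float = 0.0516
    ka_off: float = 1.58
    kr_on: float = 0.0277
    kr_off: float = 0.075
    k_loop: float = 0.592
    k_unloop: float = 0.151
    k_loop_diss: float = 0.0441
    k_tx_active: float = 6.89
    k_tx_basal: float = 0.0836
    b_d1: float = 7.48
    b_d2: float = 7.48
    k_tl: float = 8.59
    gamma_m: float = 0.403
    v_max: float = 373.0
    k_m: float = 5.17
    dilution: float = 0.028
    ara_k_half: float = 0.251
    ara_hill: float = 3.0
    ara_basal: float = 0.00142
    iptg_laci_k_half: float = 0.861
    iptg_laci_hill: float = 1.0
    iptg_ara_k_inhib: float = 23.5
    arac_assembly_k: float = 0.0
    laci_assembly_k: float = 0.0

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if v < 0:
                raise ValueError(f"parameter {f.name} must be nonnegative, got {v}")
        if self.ara_hill < 1 or self.iptg_laci_hill < 1:
            raise ValueError("Hill exponents must be >= 1")
        if self.k_m <= 0:
            raise ValueError("k_m must be positive")
        if not 0 <= self.ara_basal <= 1:
            raise ValueError("ara_basal is a fraction in [0, 1]")

    def with_b_d2_scaled(self, factor: float) -> "ParameterSet":
        """Return a copy with the lac-reporter maximum rate scaled.

        Used by the robustness scan, which multiplies ``b_d2`` by a scalar
        >= 1 while leaving every other field untouched.
        """
        if factor < 1:
            raise ValueError(f"b_d2 scale factor must be >= 1, got {factor}")
        return dataclasses.replace(self, b_d2=self.b_d2 * factor)

    def replace(self, **kwargs) -> "ParameterSet":
        return dataclasses.replace(self, **kwargs)


DEFAULT_PARAMETERS = ParameterSet()

#: Provenance of every default value.  No deposited parameter table exists
#: for this circuit family in a machine-readable form, so defaults are either
#: order-of-magnitude literature values for the underlying biochemistry or
#: values fixed once so that the default model reproduces the documented
#: regime structure (oscillation at high arabinose and low-to-moderate IPTG,
#: stable fixed points at low arabinose and, for the lac-reporter circuit,
#: at high IPTG).  See docs/methods.md for the reasoning.
PROVENANCE: dict[str, str] = {
    "ka_on": "calibrated: fast per-dimer association at the AraC half-site",
    "ka_off": "calibrated: sub-minute activator residence (fast arm)",
    "kr_on": "calibrated: LacI-operator association; with kr_off gives a "
             "repression threshold of a few free tetramers",
    "kr_off": "calibrated: slow operator dissociation (~13 min residence); "
              "the slow DNA-binding stage is the repressor arm's delay",
    "k_loop": "calibrated: looping a few-minute step after single binding",
    "k_unloop": "calibrated: loop opening slower than formation",
    "k_loop_diss": "calibrated: ~23 min loop persistence (repression memory)",
    "k_tx_active": "calibrated: activated transcription per promoter copy",
    "k_tx_basal": "calibrated: ~1% leak of the activated rate",
    "b_d1": "set equal to b_d2 (the two reporter promoters share a maximum)",
    "b_d2": "calibrated: reporter maximum transcription rate",
    "k_tl": "chosen: several protein monomers per transcript per minute",
    "gamma_m": "chosen: ~1.7 min mRNA half-life",
    "v_max": "calibrated: limited ClpXP capacity, saturated at circuit load",
    "k_m": "calibrated: a few molecules; deep saturation drives the "
           "degrade-and-fire crash",
    "dilution": "chosen: ~25 min doubling time",
    "ara_k_half": "calibrated: upper-middle of the 0.01-1.0 % sweep range",
    "ara_hill": "chosen: cooperative arabinose uptake/response",
    "ara_basal": "chosen: ~0.1% leaky AraC activity without arabinose",
    "iptg_laci_k_half": "calibrated: mid-log of the 0.001-31.6 mM sweep range",
    "iptg_laci_hill": "chosen: non-cooperative IPTG binding",
    "iptg_ara_k_inhib": "chosen: weak inhibition (half-effect near sweep max)",
    "arac_assembly_k": "calibrated: dimer assembly scale of the active pool",
    "laci_assembly_k": "calibrated: tetramer assembly scale of the active pool",
}


def _reject_unknown(section: dict, cls, label: str) -> dict:
    known = {f.name for f in fields(cls)}
    unknown = set(section) - known
    if unknown:
        raise ValueError(f"unknown {label} keys: {sorted(unknown)}")
    return section


def load_config(path: str | Path) -> tuple[CircuitConfig, ParameterSet]:
    """Read a circuit + parameter configuration from a YAML or JSON file.

    The file holds two optional mappings, ``circuit`` and ``parameters``;
    omitted fields fall back to the defaults and unknown keys are rejected.
    """
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ValueError(f"config root must be a mapping, got {type(data).__name__}")
    unknown = set(data) - {"circuit", "parameters"}
    if unknown:
        raise ValueError(f"unknown config sections: {sorted(unknown)}")
    circuit = CircuitConfig(**_reject_unknown(data.get("circuit", {}) or {},
                                              CircuitConfig, "circuit"))
    params = ParameterSet(**_reject_unknown(data.get("parameters", {}) or {},
                                            ParameterSet, "parameter"))
    return circuit, params
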