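"""Promoter microstate enumeration.

Each promoter class is a small continuous-time Markov scheme over site
occupancy patterns; the assembled ODE system (:mod:`dualosc.odes`) turns the
scheme into master equations for the occupancy (copies/cell) of every state.

Site grammar
------------
* An AraC half-site is either empty (``0``) or bound by one AraC dimer
  (``1``); promoters without the site carry ``None``.
* A pair of lac operators takes one of five patterns: ``E`` (empty), ``O1``
  or ``O2`` (one tetramer on that operator), ``B`` (two tetramers, one per
  operator) or ``L`` (a single tetramer bridging both operators in a DNA
  loop).  The loop forms from a singly bound pattern at ``k_loop``, opens
  back to a singly bound pattern at ``k_unloop`` (split evenly over the two
  exits) and falls off DNA entirely at ``k_loop_diss``, releasing its
  tetramer.

Transcriptional activity: any LacI occupancy silences the promoter; an
AraC-dependent promoter transcribes at the activated rate with AraC bound
and at the basal rate otherwise; the lac reporter promoter (no AraC site)
transcribes at its maximum whenever unrepressed; the decoy never transcribes.
"""

from __future__ import annotations

from dataclasses import dataclass

PROMOTER_KINDS = (
    "lac_ara_regulatory",
    "lac_ara_reporter",
    "lac_reporter",
    "arac_decoy",
)

LAC_PATTERNS = ("E", "O1", "O2", "B", "L")

#: tetramers sequestered on DNA per promoter copy, by lac pattern
_LAC_LOAD = {"E": 0, "O1": 1, "O2": 1, "B": 2, "L": 1}


@dataclass(frozen=True)
class Transition:
    """One directed microstate transition of a promoter scheme.

    ``rate_param`` names the :class:`~dualosc.params.ParameterSet` field
    giving the base rate; ``multiplier`` scales it; ``pool`` names the free
    protein pool (``"arac"``/``"laci"``) whose abundance multiplies the rate
    for bimolecular (binding) steps, or ``None`` for unimolecular steps.
    ``d_arac``/``d_laci`` are the molecules released to (+1) or taken from
    (-1) the free pools when the transition fires.
    """

    src: int
    dst: int
    rate_param: str
    pool: str | None = None
    multiplier: float = 1.0
    d_arac: int = 0
    d_laci: int = 0


@dataclass(frozen=True)
class PromoterModel:
    """Enumerated microstates, transitions and per-state activity."""

    promoter_kind: str
    states: tuple[tuple, ...]          # (arac, lac_pattern) labels
    transitions: tuple[Transition, ...]
    activity_params: tuple[str | None, ...]  # ParameterSet field or None

    @property
    def n_states(self) -> int:
        return len(self.states)

    @property
    def unbound_index(self) -> int:
        """Index of the unique fully-unbound state."""
        for i, (arac, pat) in enumerate(self.states):
            if arac in (0, None) and pat in ("E", None):
                return i
        raise AssertionError("no unbound state")  # pragma: no cover

    def state_label(self, i: int) -> str:
        arac, pat = self.states[i]
        bits = []
        if arac is not None:
            bits.append(f"ara{arac}")
        if pat is not None:
            bits.append(pat)
        return "_".join(bits)

    def activity_rates(self, params) -> list[float]:
        """Transcription rate of each state under ``params`` (mRNA/copy/min)."""
        return [0.0 if p is None else getattr(params, p)
                for p in self.activity_params]

    def laci_load(self, i: int) -> int:
        """LacI tetramers held on DNA in state ``i`` (per promoter copy)."""
        _, pat = self.states[i]
        return 0 if pat is None else _LAC_LOAD[pat]

    def arac_load(self, i: int) -> int:
        arac, _ = self.states[i]
        return 0 if arac in (None, 0) else 1


def _lac_transitions(index: dict, arac_values: tuple) -> list[Transition]:
    """LacI operator transitions replicated for every AraC sub-state."""
    edges = []
    for a in arac_values:
        s = {pat: index[(a, pat)] for pat in LAC_PATTERNS}
        for single in ("O1", "O2"):
            edges += [
                Transition(s["E"], s[single], "kr_on", pool="laci", d_laci=-1),
                Transition(s[single], s["E"], "kr_off", d_laci=+1),
                Transition(s[single], s["B"], "kr_on", pool="laci", d_laci=-1),
                Transition(s["B"], s[single], "kr_off", d_laci=+1),
                # the bound tetramer itself bridges the other operator
                Transition(s[single], s["L"], "k_loop"),
                Transition(s["L"], s[single], "k_unloop", multiplier=0.5),
            ]
        edges.append(Transition(s["L"], s["E"], "k_loop_diss", d_laci=+1))
    return edges


def _arac_transitions(index: dict, lac_values: tuple) -> list[Transition]:
    edges = []
    for pat in lac_values:
        on = index[(1, pat)]
        off = index[(0, pat)]
        edges += [
            Transition(off, on, "ka_on", pool="arac", d_arac=-1),
            Transition(on, off, "ka_off", d_arac=+1),
        ]
    return edges


def build_promoter_model(promoter_kind: str) -> PromoterModel:
    """Enumerate the microstate scheme for one promoter class.

    ``lac_ara_regulatory`` and ``lac_ara_reporter`` share the 10-state
    product scheme (2 AraC-site states x 5 LacI patterns) and differ only in
    which maximum transcription rate applies; ``lac_reporter`` keeps the 5
    LacI patterns; ``arac_decoy`` is a bare bound/unbound AraC site with no
    transcription.
    """
    if promoter_kind not in PROMOTER_KINDS:
        raise ValueError(
            f"unknown promoter_kind {promoter_kind!r}; expected one of "
            f"{PROMOTER_KINDS}"
        )

    if promoter_kind in ("lac_ara_regulatory", "lac_ara_reporter"):
        states = tuple((a, pat) for a in (0, 1) for pat in LAC_PATTERNS)
        index = {s: i for i, s in enumerate(states)}
        transitions = _lac_transitions(index, (0, 1)) + _arac_transitions(
            index, LAC_PATTERNS
        )
        active = "k_tx_active" if promoter_kind == "lac_ara_regulatory" else "b_d1"
        activity = tuple(
            (active if a == 1 else "k_tx_basal") if pat == "E" else None
            for (a, pat) in states
        )
    elif promoter_kind == "lac_reporter":
        states = tuple((None, pat) for pat in LAC_PATTERNS)
        index = {s: i for i, s in enumerate(states)}
        transitions = _lac_transitions(index, (None,))
        activity = tuple("b_d2" if pat == "E" else None for (_, pat) in states)
    else:  # arac_decoy
        states = ((0, None), (1, None))
        transitions = [
            Transition(0, 1, "ka_on", pool="arac", d_arac=-1),
            Transition(1, 0, "ka_off", d_arac=+1),
        ]
        activity = (None, None)

    return PromoterModel(
        promoter_kind=promoter_kind,
        states=states,
        transitions=tuple(transitions),
        activity_params=activity,
    )
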