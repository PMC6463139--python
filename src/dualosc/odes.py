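"""Assembly of the full deterministic ODE system for one circuit variant.

State vector layout (molecules/cell):

* free functional AraC dimers ``a`` and LacI tetramers ``l``, free GFP ``g``
  (``g`` is present only when a reporter gene exists);
* mRNA pools per gene (default; a lumped quasi-steady-mRNA mode exists for
  testing);
* occupancy of every promoter microstate for every promoter class, in
  copies/cell.  Master equations move occupancy between microstates, so the
  per-class occupancy sum is conserved exactly at the DNA copy number.

Binding transitions consume free protein; unbinding and loop dissociation
release it.  Downstream classes (reporter promoter, decoy) stop consuming
when retroactivity is toggled off but their occupancy still evolves ("sense
but do not consume").  All SsrA-tagged proteins are degraded by a shared
saturable protease; with protease sharing toggled off, GFP moves to an
independent channel with identical kinetics.  First-order dilution acts on
free proteins and mRNA, not on DNA.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from dualosc.params import CircuitConfig, InducerCondition, ParameterSet
from dualosc.promoters import PromoterModel, build_promoter_model


def active_fractions(
    condition: InducerCondition, params: ParameterSet
) -> tuple[float, float]:
    """Inducer response: (AraC activation fraction, LacI active fraction).

    The AraC fraction multiplies the DNA on-rate ``ka_on``; it rises with
    arabinose (Hill curve with floor ``ara_basal``) and IPTG weakly inhibits
    only the arabinose-dependent part, so the floor is IPTG-independent.
    The LacI fraction multiplies ``kr_on`` and falls with IPTG (Hill curve,
    half-effect at ``iptg_laci_k_half``).  Both lie in [0, 1].
    """
    ara, iptg = condition.arabinose, condition.iptg
    if ara < 0 or iptg < 0:
        raise ValueError("inducer concentrations must be nonnegative")
    if ara == 0:
        hill_ara = 0.0
    else:
        r = (ara / params.ara_k_half) ** params.ara_hill
        hill_ara = r / (1.0 + r)
    inhib = 1.0 / (1.0 + iptg / params.iptg_ara_k_inhib)
    f_arac = params.ara_basal + (1.0 - params.ara_basal) * hill_ara * inhib

    if iptg == 0:
        f_laci = 1.0
    else:
        s = (iptg / params.iptg_laci_k_half) ** params.iptg_laci_hill
        f_laci = 1.0 / (1.0 + s)
    return f_arac, f_laci


def degradation_flux(
    pools, params: ParameterSet, sharing_on: bool
) -> np.ndarray:
    """Protease degradation rates of the free (a, l, g) pools.

    With sharing on, the three tagged species compete for one enzyme:
    ``flux_x = v_max * x / (k_m + a + l + g)``, so the summed flux is a
    single-enzyme Michaelis-Menten rate and never exceeds ``v_max``.  With
    sharing off, AraC and LacI keep a shared denominator (they are always
    co-substrates of the circuit's protease) while GFP is served by an
    independent channel with the same ``v_max`` and ``k_m``.
    """
    a, l, g = (float(x) for x in pools)
    if sharing_on:
        denom = params.k_m + a + l + g
        return params.v_max * np.array([a, l, g]) / denom
    denom_al = params.k_m + a + l
    denom_g = params.k_m + g
    return np.array(
        [params.v_max * a / denom_al,
         params.v_max * l / denom_al,
         params.v_max * g / denom_g]
    )


@dataclass
class _ClassArrays:
    """Precompiled per-promoter-class arrays for fast RHS evaluation."""

    name: str
    model: PromoterModel
    copy_number: int
    offset: int               # index of the class block in the state vector
    consumes: bool            # does binding deplete the free pools?
    product: str | None       # 'araC' | 'lacI' | 'gfp' | None
    src: np.ndarray = field(default=None)
    dst: np.ndarray = field(default=None)
    base: np.ndarray = field(default=None)      # rate with inducer factors folded in
    pool_code: np.ndarray = field(default=None)  # 0 none, 1 arac, 2 laci
    d_arac: np.ndarray = field(default=None)
    d_laci: np.ndarray = field(default=None)
    stoich: np.ndarray = field(default=None)    # n_states x n_transitions
    activity: np.ndarray = field(default=None)  # mRNA/min per state occupancy

    @property
    def sl(self) -> slice:
        return slice(self.offset, self.offset + self.model.n_states)


_POOL_CODE = {None: 0, "arac": 1, "laci": 2}
_MULTIMER = {"araC": 2.0, "lacI": 4.0, "gfp": 1.0}


class ODESystem:
    """Right-hand side, analytic Jacobian and bookkeeping for one circuit.

    Built by :func:`assemble_odes`; the inducer condition is folded into the
    promoter rate constants at assembly time, so evaluation only needs the
    state vector.
    """

    def __init__(
        self,
        config: CircuitConfig,
        params: ParameterSet,
        condition: InducerCondition,
        explicit_mrna: bool = True,
    ):
        self.config = config
        self.params = params
        self.condition = condition
        self.explicit_mrna = explicit_mrna
        self.has_reporter = config.reporter_kind != "none"
        self.f_arac, self.f_laci = active_fractions(condition, params)
        self._build_layout()
        self._compile_classes()

    # -- layout -----------------------------------------------------------

    def _build_layout(self) -> None:
        names = ["arac_free", "laci_free"]
        self.i_a, self.i_l = 0, 1
        self.i_g = None
        if self.has_reporter:
            self.i_g = len(names)
            names.append("gfp")
        self.i_m = {}
        if self.explicit_mrna:
            genes = ["araC", "lacI"] + (["gfp"] if self.has_reporter else [])
            for gene in genes:
                self.i_m[gene] = len(names)
                names.append(f"mrna_{gene}")

        spec: list[tuple[str, str, int, bool, str | None]] = [
            ("reg_activator", "lac_ara_regulatory",
             self.config.n_activator_dna, False, "araC"),
            ("reg_repressor", "lac_ara_regulatory",
             self.config.n_repressor_dna, False, "lacI"),
        ]
        kind = self.config.reporter_kind
        if kind == "lac_ara":
            spec.append(("reporter", "lac_ara_reporter",
                         self.config.n_activator_dna, True, "gfp"))
        elif kind in ("lac", "lac_decoy"):
            spec.append(("reporter", "lac_reporter",
                         self.config.n_activator_dna, True, "gfp"))
        if kind == "lac_decoy":
            spec.append(("decoy", "arac_decoy",
                         self.config.n_activator_dna, True, None))

        self.classes: list[_ClassArrays] = []
        for name, pkind, copies, downstream, product in spec:
            model = build_promoter_model(pkind)
            consumes = (not downstream) or self.config.retroactivity_on
            cls = _ClassArrays(
                name=name, model=model, copy_number=copies,
                offset=len(names), consumes=consumes, product=product,
            )
            names += [f"{name}:{model.state_label(i)}"
                      for i in range(model.n_states)]
            self.classes.append(cls)
        self.state_names: list[str] = names
        self.n = len(names)

    def _compile_classes(self) -> None:
        for cls in self.classes:
            trs = cls.model.transitions
            cls.src = np.array([t.src for t in trs])
            cls.dst = np.array([t.dst for t in trs])
            cls.base = np.array(
                [getattr(self.params, t.rate_param) * t.multiplier
                 for t in trs]
            )
            cls.pool_code = np.array([_POOL_CODE[t.pool] for t in trs])
            cls.d_arac = np.array([float(t.d_arac) for t in trs])
            cls.d_laci = np.array([float(t.d_laci) for t in trs])
            stoich = np.zeros((cls.model.n_states, len(trs)))
            for k, t in enumerate(trs):
                stoich[t.src, k] -= 1.0
                stoich[t.dst, k] += 1.0
            cls.stoich = stoich
            cls.activity = np.array(cls.model.activity_rates(self.params))

    # -- initial state ----------------------------------------------------

    def initial_state(self, a: float = 10.0, l: float = 10.0) -> np.ndarray:
        """All DNA unbound, a small free-protein seed, no mRNA or GFP."""
        y = np.zeros(self.n)
        y[self.i_a], y[self.i_l] = a, l
        for cls in self.classes:
            y[cls.offset + cls.model.unbound_index] = cls.copy_number
        return y

    @property
    def conserved_blocks(self) -> list[tuple[slice, float]]:
        """(state slice, conserved total) for every promoter class."""
        return [(cls.sl, float(cls.copy_number)) for cls in self.classes]

    @property
    def conservation_matrix(self) -> np.ndarray:
        """Rows are exact linear invariants (per-class occupancy sums).

        Each row ``c`` satisfies ``c @ rhs(y) == 0`` identically, so the
        Jacobian always carries one structural zero eigenvalue per promoter
        class; stability analysis must classify on the invariant manifold
        (see :func:`dualosc.stability.find_equilibria`).
        """
        C = np.zeros((len(self.classes), self.n))
        for i, cls in enumerate(self.classes):
            C[i, cls.sl] = 1.0
        return C

    # -- dynamics ---------------------------------------------------------

    def _check_dim(self, y: np.ndarray) -> np.ndarray:
        y = np.asarray(y, dtype=float)
        if y.shape != (self.n,):
            raise ValueError(
                f"state dimension {y.shape} does not match system "
                f"dimension ({self.n},) for reporter_kind="
                f"{self.config.reporter_kind!r}"
            )
        return y

    def _binding_pools(self, a: float, l: float) -> tuple[float, float]:
        """DNA-binding-competent pools: inducer response plus fast
        multimer-assembly equilibrium of the active pool."""
        x = self.f_arac * a
        ka = self.params.arac_assembly_k
        pa = x if ka == 0.0 else x * x / (x + ka)
        z = self.f_laci * l
        kl = self.params.laci_assembly_k
        pl = z if kl == 0.0 else z * z / (z + kl)
        return pa, pl

    def _binding_pool_derivs(self, a: float, l: float) -> tuple[float, float]:
        x = self.f_arac * a
        ka = self.params.arac_assembly_k
        da = self.f_arac * (1.0 if ka == 0.0
                            else (x * x + 2.0 * x * ka) / (x + ka) ** 2)
        z = self.f_laci * l
        kl = self.params.laci_assembly_k
        dl = self.f_laci * (1.0 if kl == 0.0
                            else (z * z + 2.0 * z * kl) / (z + kl) ** 2)
        return da, dl

    def rhs(self, t: float, y: np.ndarray) -> np.ndarray:
        y = self._check_dim(y)
        p = self.params
        a, l = y[self.i_a], y[self.i_l]
        dy = np.zeros(self.n)
        tx = {"araC": 0.0, "lacI": 0.0, "gfp": 0.0}

        pool_a, pool_l = self._binding_pools(a, l)
        pool_vals = np.array([1.0, pool_a, pool_l])
        for cls in self.classes:
            occ = y[cls.sl]
            flux = cls.base * pool_vals[cls.pool_code] * occ[cls.src]
            dy[cls.sl] += cls.stoich @ flux
            if cls.consumes:
                dy[self.i_a] += cls.d_arac @ flux
                dy[self.i_l] += cls.d_laci @ flux
            if cls.product is not None:
                tx[cls.product] += cls.activity @ occ

        lam = p.dilution
        prod = {}
        for gene in ("araC", "lacI", "gfp"):
            if gene == "gfp" and not self.has_reporter:
                continue
            rate_tl = p.k_tl / _MULTIMER[gene]
            if self.explicit_mrna:
                im = self.i_m[gene]
                dy[im] += tx[gene] - (p.gamma_m + lam) * y[im]
                prod[gene] = rate_tl * y[im]
            else:
                prod[gene] = rate_tl * tx[gene] / (p.gamma_m + lam)

        g = y[self.i_g] if self.has_reporter else 0.0
        deg = degradation_flux((a, l, g), p, self.config.protease_sharing_on)
        dy[self.i_a] += prod["araC"] - deg[0] - lam * a
        dy[self.i_l] += prod["lacI"] - deg[1] - lam * l
        if self.has_reporter:
            dy[self.i_g] += prod["gfp"] - deg[2] - lam * g
        return dy

    def jacobian(self, t: float, y: np.ndarray) -> np.ndarray:
        """Analytic Jacobian of :meth:`rhs` (exact for the assembled terms)."""
        y = self._check_dim(y)
        p = self.params
        a, l = y[self.i_a], y[self.i_l]
        J = np.zeros((self.n, self.n))
        pool_a, pool_l = self._binding_pools(a, l)
        dpool_a, dpool_l = self._binding_pool_derivs(a, l)
        pool_vals = np.array([1.0, pool_a, pool_l])
        pool_col = {1: self.i_a, 2: self.i_l}
        pool_der = {1: dpool_a, 2: dpool_l}

        for cls in self.classes:
            occ = y[cls.sl]
            off = cls.offset
            for k in range(len(cls.src)):
                s, d = off + cls.src[k], off + cls.dst[k]
                code = cls.pool_code[k]
                rate = cls.base[k] * pool_vals[code]
                # d flux / d occ_src
                J[s, s] -= rate
                J[d, s] += rate
                if cls.consumes:
                    J[self.i_a, s] += cls.d_arac[k] * rate
                    J[self.i_l, s] += cls.d_laci[k] * rate
                if code:
                    col = pool_col[code]
                    dr = cls.base[k] * occ[cls.src[k]] * pool_der[code]
                    J[s, col] -= dr
                    J[d, col] += dr
                    if cls.consumes:
                        J[self.i_a, col] += cls.d_arac[k] * dr
                        J[self.i_l, col] += cls.d_laci[k] * dr
            if cls.product is not None and self.explicit_mrna:
                J[self.i_m[cls.product], cls.sl] += cls.activity
            elif cls.product is not None:
                row = {"araC": self.i_a, "lacI": self.i_l,
                       "gfp": self.i_g}[cls.product]
                coef = p.k_tl / _MULTIMER[cls.product] / (p.gamma_m + p.dilution)
                J[row, cls.sl] += coef * cls.activity

        lam = p.dilution
        if self.explicit_mrna:
            for gene, im in self.i_m.items():
                J[im, im] -= p.gamma_m + lam
                row = {"araC": self.i_a, "lacI": self.i_l,
                       "gfp": self.i_g}[gene]
                J[row, im] += p.k_tl / _MULTIMER[gene]

        # degradation + dilution of free pools
        g = y[self.i_g] if self.has_reporter else 0.0
        rows = [self.i_a, self.i_l] + ([self.i_g] if self.has_reporter else [])
        vals = [a, l] + ([g] if self.has_reporter else [])
        if self.config.protease_sharing_on:
            denom = p.k_m + a + l + g
            for ri, xi in zip(rows, vals):
                for rj, xj in zip(rows, vals):
                    J[ri, rj] -= p.v_max * (
                        (denom - xi) / denom**2 if ri == rj
                        else -xi / denom**2
                    )
        else:
            denom = p.k_m + a + l
            for ri, xi in zip(rows[:2], vals[:2]):
                for rj, xj in zip(rows[:2], vals[:2]):
                    J[ri, rj] -= p.v_max * (
                        (denom - xi) / denom**2 if ri == rj
                        else -xi / denom**2
                    )
            if self.has_reporter:
                dg = p.k_m + g
                J[self.i_g, self.i_g] -= p.v_max * p.k_m / dg**2
        for ri in rows:
            J[ri, ri] -= lam
        return J

    # convenience callables matching scipy's (t, y) signature
    def __call__(self, t: float, y: np.ndarray) -> np.ndarray:
        return self.rhs(t, y)


def assemble_odes(
    config: CircuitConfig,
    params: ParameterSet,
    condition: InducerCondition,
    explicit_mrna: bool = True,
) -> ODESystem:
    """Build the deterministic ODE system for one circuit and condition.

    ``explicit_mrna=False`` replaces the mRNA stage by its quasi-steady
    state (production proportional to instantaneous transcription), which
    shrinks the system for tests; the default keeps transcription,
    translation and mRNA decay explicit.
    """
    return ODESystem(config, params, condition, explicit_mrna=explicit_mrna)
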