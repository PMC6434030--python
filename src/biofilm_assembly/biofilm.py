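"""Steady-state 1-D multispecies reaction-diffusion model of biofilm oxygen.

Solutes (dissolved oxygen, ammonium-N, nitrite-N, soluble organics as COD)
diffuse across a biofilm of thickness ``L`` and are consumed by three guilds
— aerobic heterotrophs, ammonia oxidizers (AOB) and nitrite oxidizers (NOB)
— with dual-Monod kinetics.  For every solute ``k`` the two-point boundary
value problem

    D_k * d2S_k/dz2  -  sum_j nu_kj * r_j(z, S)  =  0
    r_j = q_max_j * f * X(z) * fraction_j(z) * prod_i S_i/(K_i + S_i)

is solved with zero flux at the substratum (z = 0) and flux continuity
through a diffusive boundary layer of thickness ``L_BL`` at the
biofilm-liquid interface:  D_w*(S_bulk - S(L))/L_BL = D_f*dS/dz|_L.

Stoichiometry: heterotrophs consume organics plus ``1 - 1.42*Y_H`` g O2 per
g COD; AOB consume 3.43 g O2 per g NH4-N oxidized and produce NO2-N 1:1;
NOB consume 1.14 g O2 per g NO2-N.  The model resolves heterogeneity in the
depth direction only — layers parallel to the substratum are homogeneous and
there is no lateral transport.

Numerics: conservative vertex-centred finite volumes on a uniform grid,
damped Newton iteration with an analytic sparse Jacobian, concentrations
clipped at zero between iterates.  Because the scheme is conservative, the
interface flux equals the depth-integrated net consumption to solver
tolerance for every solute.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np
import yaml
from scipy.sparse import coo_matrix
from scipy.sparse.linalg import spsolve

SOLUTES = ("do", "nh4", "no2", "cod")

UM = 1e-6  # metres per micrometre


@dataclass
class GuildKinetics:
    """Monod kinetics of one guild.

    ``q_max`` is the maximum specific substrate conversion rate
    (g substrate / g active biomass / d); ``gamma_o2`` the oxygen demand per
    g substrate converted (g O2/g); ``product`` an optional solute produced
    1:1 (as mass of the shared element, e.g. NO2-N per NH4-N).
    """

    substrate: str  # consumed solute
    q_max: float  # g substrate / g biomass / d
    K_sub: float  # mg/L
    K_o2: float  # mg/L
    gamma_o2: float  # g O2 / g substrate
    product: str | None = None

    def __post_init__(self) -> None:
        if self.q_max < 0 or self.K_sub <= 0 or self.K_o2 <= 0 or self.gamma_o2 < 0:
            raise ValueError("kinetic constants must be positive (q_max, gamma >= 0)")
        if self.substrate not in SOLUTES or (
            self.product is not None and self.product not in SOLUTES
        ):
            raise ValueError(f"solutes must be among {SOLUTES}")


def default_kinetics() -> dict[str, GuildKinetics]:
    """Activated-sludge/nitrifier literature-style constants (editable).

    Heterotrophs: q 8 gCOD/gX/d, Y_H 0.45 gVSS/gCOD so gamma_O2 =
    1 - 1.42*0.45 = 0.361 gO2/gCOD.  AOB: q 5 gN/gX/d, gamma 3.43 gO2/gN.
    NOB: q 8 gN/gX/d, gamma 1.14 gO2/gN.
    """
    return {
        "het": GuildKinetics("cod", q_max=8.0, K_sub=5.0, K_o2=0.2, gamma_o2=0.361),
        "aob": GuildKinetics("nh4", q_max=5.0, K_sub=1.0, K_o2=0.5, gamma_o2=3.43,
                             product="no2"),
        "nob": GuildKinetics("no2", q_max=8.0, K_sub=0.5, K_o2=0.68, gamma_o2=1.14),
    }


def default_diffusivities() -> tuple[dict[str, float], dict[str, float]]:
    """(film, water) diffusivities in m^2/d; film = 0.8 x water."""
    water = {"do": 1.90e-4, "nh4": 1.70e-4, "no2": 1.60e-4, "cod": 1.00e-4}
    film = {k: 0.8 * v for k, v in water.items()}
    return film, water


def _profile_array(profile, rel_depth: np.ndarray) -> np.ndarray:
    """Evaluate a scalar or (relative depth, value) breakpoint profile."""
    if np.isscalar(profile):
        return np.full_like(rel_depth, float(profile))
    pts = np.asarray(profile, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("profile must be a scalar or an array of (rel_depth, value)")
    return np.interp(rel_depth, pts[:, 0], pts[:, 1])


@dataclass
class BiofilmConfig:
    """Geometry, bulk conditions, biomass profiles and kinetics of one run.

    ``density_profile`` (kg dry solids / m^3) and each guild fraction may be
    a scalar or a list of (relative depth, value) breakpoints, relative depth
    0 at the substratum and 1 at the interface.  ``active_fraction`` is the
    fraction of the dry solids that is active biomass (the 20-80% scenario
    dial); ``boundary_layer_um = 0`` pins the interface to bulk
    concentrations.
    """

    thickness_um: float = 400.0
    n_nodes: int = 200
    bulk: dict = field(
        default_factory=lambda: {"do": 5.5, "nh4": 19.6, "no2": 0.5, "cod": 30.0}
    )
    density_profile: object = 40.0
    guild_fractions: dict = field(
        default_factory=lambda: {"het": 0.4, "aob": 0.3, "nob": 0.1}
    )
    active_fraction: float = 0.5
    boundary_layer_um: float = 50.0
    kinetics: dict = field(default_factory=default_kinetics)
    diffusivity_film: dict = field(default_factory=lambda: default_diffusivities()[0])
    diffusivity_water: dict = field(default_factory=lambda: default_diffusivities()[1])
    anoxia_threshold: float = 0.1  # mg O2 / L

    def __post_init__(self) -> None:
        if self.thickness_um <= 0:
            raise ValueError("thickness must be positive")
        if not (0.0 < self.active_fraction <= 1.0):
            raise ValueError("active_fraction must be in (0, 1]")
        if self.n_nodes < 10:
            raise ValueError("need >= 10 grid nodes")
        if self.boundary_layer_um < 0:
            raise ValueError("boundary layer thickness must be >= 0")
        for k in SOLUTES:
            if self.bulk.get(k, 0.0) < 0:
                raise ValueError(f"bulk concentration of {k} must be >= 0")
            if self.diffusivity_film[k] <= 0 or self.diffusivity_water[k] <= 0:
                raise ValueError("diffusivities must be positive")
        rel = np.linspace(0, 1, 5)
        for g, prof in self.guild_fractions.items():
            vals = _profile_array(prof, rel)
            if (vals < 0).any() or (vals > 1).any():
                raise ValueError(f"guild fraction of {g} must lie in [0, 1]")
        if (_profile_array(self.density_profile, rel) < 0).any():
            raise ValueError("density must be >= 0")

    def copy(self) -> "BiofilmConfig":
        return copy.deepcopy(self)

    def to_yaml(self, path) -> None:
        d = {
            "thickness_um": self.thickness_um,
            "n_nodes": self.n_nodes,
            "bulk": dict(self.bulk),
            "density_profile": self.density_profile
            if np.isscalar(self.density_profile)
            else np.asarray(self.density_profile).tolist(),
            "guild_fractions": {
                g: (p if np.isscalar(p) else np.asarray(p).tolist())
                for g, p in self.guild_fractions.items()
            },
            "active_fraction": self.active_fraction,
            "boundary_layer_um": self.boundary_layer_um,
            "kinetics": {
                g: {
                    "substrate": k.substrate,
                    "q_max": k.q_max,
                    "K_sub": k.K_sub,
                    "K_o2": k.K_o2,
                    "gamma_o2": k.gamma_o2,
                    "product": k.product,
                }
                for g, k in self.kinetics.items()
            },
            "diffusivity_film": dict(self.diffusivity_film),
            "diffusivity_water": dict(self.diffusivity_water),
            "anoxia_threshold": self.anoxia_threshold,
        }
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "BiofilmConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        if "kinetics" in d:
            d["kinetics"] = {g: GuildKinetics(**kk) for g, kk in d["kinetics"].items()}
        return cls(**d)


def z50_config(**overrides) -> BiofilmConfig:
    """Thin (50 um), dense biofilm with depth-uniform guild composition."""
    kw = dict(
        thickness_um=50.0,
        density_profile=100.0,
        guild_fractions={"het": 0.5, "aob": 0.35, "nob": 0.15},
    )
    kw.update(overrides)
    return BiofilmConfig(**kw)


def z400_config(**overrides) -> BiofilmConfig:
    """Thick (400 um) biofilm: less dense, AOB enriched in the upper third,
    NOB in the middle (FISH-style depth profiles supplied as data)."""
    kw = dict(
        thickness_um=400.0,
        density_profile=[[0.0, 60.0], [1.0, 30.0]],
        guild_fractions={
            "het": [[0.0, 0.30], [1.0, 0.40]],
            "aob": [[0.0, 0.05], [0.6, 0.10], [0.75, 0.35], [1.0, 0.35]],
            "nob": [[0.0, 0.05], [0.3, 0.20], [0.6, 0.20], [0.8, 0.05], [1.0, 0.05]],
        },
    )
    kw.update(overrides)
    return BiofilmConfig(**kw)


@dataclass
class DOProfile:
    """Depth-resolved steady-state solution of one configuration."""

    depth_um: np.ndarray  # 0 at substratum, L at interface
    concentrations: dict  # solute -> mg/L per node
    interface_flux: dict  # solute -> g/m^2/d into the biofilm
    integrated_consumption: dict  # solute -> net g/m^2/d
    anoxic_fraction: float
    converged: bool
    residual: float
    n_iterations: int

    def anoxic_depth_um(self, threshold: float | None = None) -> float:
        """Total depth (um) with DO below the anoxia threshold."""
        return self.anoxic_fraction * float(self.depth_um[-1])


def _interval_measure_below(z: np.ndarray, s: np.ndarray, threshold: float) -> float:
    """Length of {z : s(z) < threshold} for a piecewise-linear profile."""
    total = 0.0
    for i in range(len(z) - 1):
        a, b = s[i], s[i + 1]
        dz = z[i + 1] - z[i]
        if a < threshold and b < threshold:
            total += dz
        elif a < threshold or b < threshold:
            frac = abs(threshold - (a if a < threshold else b)) / abs(b - a)
            total += dz * frac
    return total


class BiofilmModel:
    """Newton solver and scenario tooling around one :class:`BiofilmConfig`."""

    def __init__(self, config: BiofilmConfig):
        self.config = config

    # -------------------------------------------------------------- assembly
    def _grids(self):
        c = self.config
        n = c.n_nodes
        L = c.thickness_um * UM
        z = np.linspace(0.0, L, n)
        rel = z / L
        density = _profile_array(c.density_profile, rel) * 1e3  # kg/m3 -> g/m3
        amp = {}
        for g, kin in c.kinetics.items():
            frac = _profile_array(c.guild_fractions.get(g, 0.0), rel)
            amp[g] = kin.q_max * c.active_fraction * density * frac  # g subs/m3/d
        return z, amp

    def _rates(self, S: dict, amp: dict, k_floor: float = 0.0):
        """Net consumption R (g/m3/d) and its Jacobian dR[k][m] per node.

        ``k_floor`` lower-bounds the half-saturation constants; the Newton
        continuation relaxes it to zero so that near-zero-order kinetics
        (very small K) converge from a warm start.
        """
        c = self.config
        n = c.n_nodes
        R = {k: np.zeros(n) for k in SOLUTES}
        dR = {k: {m: np.zeros(n) for m in SOLUTES} for k in SOLUTES}
        for g, kin in c.kinetics.items():
            sub = kin.substrate
            K_s = max(kin.K_sub, k_floor)
            K_o = max(kin.K_o2, k_floor)
            s_sub = np.maximum(S[sub], 0.0)
            s_o2 = np.maximum(S["do"], 0.0)
            mon_s = s_sub / (K_s + s_sub)
            mon_o = s_o2 / (K_o + s_o2)
            r = amp[g] * mon_s * mon_o
            dr_dsub = amp[g] * (K_s / (K_s + s_sub) ** 2) * mon_o
            dr_do2 = amp[g] * mon_s * (K_o / (K_o + s_o2) ** 2)
            contrib = [(sub, 1.0), ("do", kin.gamma_o2)]
            if kin.product is not None:
                contrib.append((kin.product, -1.0))
            for tgt, nu in contrib:
                R[tgt] += nu * r
                dR[tgt][sub] += nu * dr_dsub
                dR[tgt]["do"] += nu * dr_do2
        return R, dR

    def _residual(self, U: dict, amp: dict, h: float, k_floor: float = 0.0):
        c = self.config
        n = c.n_nodes
        L_bl = c.boundary_layer_um * UM
        R, dR = self._rates(U, amp, k_floor)
        F = {}
        for k in SOLUTES:
            Df = c.diffusivity_film[k]
            s = U[k]
            f = np.empty(n)
            f[0] = Df * (s[1] - s[0]) / h - R[k][0] * h / 2.0
            f[1:-1] = Df * (s[2:] - 2.0 * s[1:-1] + s[:-2]) / h - R[k][1:-1] * h
            if L_bl > 0:
                j_ext = c.diffusivity_water[k] * (c.bulk[k] - s[-1]) / L_bl
                f[-1] = j_ext - Df * (s[-1] - s[-2]) / h - R[k][-1] * h / 2.0
            else:
                f[-1] = s[-1] - c.bulk[k]
            F[k] = f
        return F, R, dR

    def _jacobian(self, dR: dict, h: float):
        c = self.config
        n = c.n_nodes
        L_bl = c.boundary_layer_um * UM
        rows, cols, vals = [], [], []
        node_w = np.full(n, h)
        node_w[0] = node_w[-1] = h / 2.0
        for ki, k in enumerate(SOLUTES):
            Df = c.diffusivity_film[k]
            base = ki * n
            # diffusion stencil
            rows += [base, base]
            cols += [base, base + 1]
            vals += [-Df / h, Df / h]
            idx = np.arange(1, n - 1)
            rows += list(base + idx) * 3
            cols += list(base + idx - 1) + list(base + idx) + list(base + idx + 1)
            vals += [Df / h] * (n - 2) + [-2.0 * Df / h] * (n - 2) + [Df / h] * (n - 2)
            if L_bl > 0:
                rows += [base + n - 1, base + n - 1]
                cols += [base + n - 1, base + n - 2]
                vals += [-c.diffusivity_water[k] / L_bl - Df / h, Df / h]
            else:
                rows.append(base + n - 1)
                cols.append(base + n - 1)
                vals.append(1.0)
            # reaction coupling
            for mi, m in enumerate(SOLUTES):
                d = dR[k][m]
                if not np.any(d):
                    continue
                stop = n if L_bl > 0 else n - 1
                idx = np.arange(0, stop)
                rows += list(base + idx)
                cols += list(mi * n + idx)
                vals += list(-d[idx] * node_w[idx])
        size = len(SOLUTES) * n
        return coo_matrix((vals, (rows, cols)), shape=(size, size)).tocsr()

    @staticmethod
    def _pack(F: dict) -> np.ndarray:
        return np.concatenate([F[k] for k in SOLUTES])

    def _newton(self, U, amp, h, scale, k_floor, max_iter):
        """Damped Newton from the warm start ``U``; returns (U, R, converged,
        residual, iterations)."""
        n = self.config.n_nodes
        F, R, dR = self._residual(U, amp, h, k_floor)
        fvec = self._pack(F)
        it = 0
        while it < max_iter:
            if np.max(np.abs(fvec) / scale) < 1e-8:
                return U, R, True, float(np.max(np.abs(fvec) / scale)), it
            it += 1
            J = self._jacobian(dR, h)
            step = spsolve(J, -fvec)
            norm0 = np.max(np.abs(fvec) / scale)
            lam = 1.0
            while True:
                U_new = {}
                for ki, k in enumerate(SOLUTES):
                    # clip at zero between iterates
                    U_new[k] = np.maximum(U[k] + lam * step[ki * n : (ki + 1) * n], 0.0)
                F_new, R_new, dR_new = self._residual(U_new, amp, h, k_floor)
                f_new = self._pack(F_new)
                if np.max(np.abs(f_new) / scale) < norm0 or lam < 1e-4:
                    break
                lam /= 2.0
            U, F, R, dR, fvec = U_new, F_new, R_new, dR_new, f_new
        return U, R, False, float(np.max(np.abs(fvec) / scale)), it

    def solve_profile(self, max_iter: int = 200) -> DOProfile:
        """Steady-state solution by damped Newton iteration.

        If the direct solve stalls (near-zero-order kinetics with very small
        half-saturation constants are stiff), a continuation is run: the
        Monod K values are floored at a sequence of decreasing values, each
        stage warm-starting the next.
        """
        c = self.config
        n = c.n_nodes
        z, amp = self._grids()
        h = z[1] - z[0]
        L = z[-1]
        U = {k: np.full(n, float(c.bulk[k])) for k in SOLUTES}

        # characteristic flux scale per solute for the convergence criterion
        R0, _ = self._rates({k: np.full(n, float(c.bulk[k])) for k in SOLUTES}, amp)
        scale = self._pack(
            {
                k: np.full(
                    n,
                    max(
                        np.abs(R0[k]).max() * L,
                        c.diffusivity_film[k] * max(c.bulk[k], 1.0) / L,
                        1e-9,
                    ),
                )
                for k in SOLUTES
            }
        )

        U, R, converged, residual, it = self._newton(U, amp, h, scale, 0.0, max_iter)
        if not converged:
            min_k = min(min(k.K_sub, k.K_o2) for k in c.kinetics.values())
            floors = [f for f in (1.0, 0.3, 0.1, 0.03, 0.01, 3e-3, 1e-3, 3e-4, 1e-4)
                      if f > min_k] + [0.0]
            U = {k: np.full(n, float(c.bulk[k])) for k in SOLUTES}
            total_it = 0
            for fl in floors:
                U, R, converged, residual, it = self._newton(
                    U, amp, h, scale, fl, max_iter
                )
                total_it += it
            it = total_it
        if not converged and residual > 1e-6:
            raise RuntimeError(
                f"biofilm solver did not converge: scaled residual {residual:.3e} "
                f"after {it} iterations"
            )
        assert all((U[k] >= 0).all() for k in SOLUTES)

        node_w = np.full(n, h)
        node_w[0] = node_w[-1] = h / 2.0
        L_bl = c.boundary_layer_um * UM
        flux, cons = {}, {}
        for k in SOLUTES:
            if L_bl > 0:
                flux[k] = float(c.diffusivity_water[k] * (c.bulk[k] - U[k][-1]) / L_bl)
            else:
                flux[k] = float(
                    c.diffusivity_film[k] * (U[k][-1] - U[k][-2]) / h + R[k][-1] * h / 2.0
                )
            cons[k] = float((R[k] * node_w).sum())

        anox = _interval_measure_below(z, U["do"], c.anoxia_threshold) / L
        return DOProfile(
            depth_um=z / UM,
            concentrations={k: U[k].copy() for k in SOLUTES},
            interface_flux=flux,
            integrated_consumption=cons,
            anoxic_fraction=float(anox),
            converged=converged,
            residual=residual,
            n_iterations=it,
        )

    # ---------------------------------------------------------- calibration
    def nh4_areal_rate(self, boundary_layer_um: float | None = None) -> float:
        """Areal ammonium oxidation rate (g N/m^2/d) at a given boundary layer."""
        cfg = self.config.copy()
        if boundary_layer_um is not None:
            cfg.boundary_layer_um = boundary_layer_um
        return BiofilmModel(cfg).solve_profile().interface_flux["nh4"]

    def calibrate_boundary_layer(
        self,
        measured_nh4_flux: float,
        bracket: tuple[float, float] = (1.0, 2000.0),
        rel_tol: float = 0.005,
        max_bisect: int = 60,
    ) -> float:
        """Bisection on L_BL until the modelled NH4 oxidation rate matches the
        measured areal rate within ``rel_tol`` (flux decreases with L_BL)."""
        lo, hi = bracket
        f_lo = self.nh4_areal_rate(lo)
        f_hi = self.nh4_areal_rate(hi)
        if not f_lo > f_hi:
            raise RuntimeError(
                "NH4 flux is not decreasing across the boundary-layer bracket"
            )
        if not (f_hi <= measured_nh4_flux <= f_lo):
            raise ValueError(
                f"measured flux {measured_nh4_flux:.4g} outside the attainable "
                f"range [{f_hi:.4g}, {f_lo:.4g}] g N/m2/d for L_BL in {bracket} um"
            )
        for _ in range(max_bisect):
            mid = 0.5 * (lo + hi)
            f_mid = self.nh4_areal_rate(mid)
            if abs(f_mid - measured_nh4_flux) <= rel_tol * abs(measured_nh4_flux):
                return mid
            if f_mid > measured_nh4_flux:
                lo = mid
            else:
                hi = mid
        return 0.5 * (lo + hi)

    # ---------------------------------------------------------------- sweeps
    def scenario_sweep(self, f_values) -> "SweepResult":
        """Solve for several active-biomass fractions and envelope the DO profiles."""
        f_values = [float(f) for f in f_values]
        if len(f_values) < 2:
            raise ValueError("need >= 2 active-fraction values")
        profiles = {}
        for f in f_values:
            cfg = self.config.copy()
            cfg.active_fraction = f
            try:
                profiles[f] = BiofilmModel(cfg).solve_profile()
            except RuntimeError as exc:
                raise RuntimeError(f"sweep member f={f} failed: {exc}") from exc
        order = sorted(f_values)
        do = np.array([profiles[f].concentrations["do"] for f in order])
        tol = 1e-6 * max(self.config.bulk["do"], 1.0)
        monotone = all(
            (do[i + 1] <= do[i] + tol).all() for i in range(len(order) - 1)
        )
        return SweepResult(
            f_values=order,
            profiles=profiles,
            depth_um=profiles[order[0]].depth_um,
            do_min=do.min(axis=0),
            do_max=do.max(axis=0),
            anoxic_fractions={f: profiles[f].anoxic_fraction for f in order},
            monotone=monotone,
        )


@dataclass
class SweepResult:
    """Envelope of DO profiles over active-biomass scenarios."""

    f_values: list[float]
    profiles: dict
    depth_um: np.ndarray
    do_min: np.ndarray
    do_max: np.ndarray
    anoxic_fractions: dict
    monotone: bool


def penetration_depth_um(profile: DOProfile, threshold: float, solute: str = "do") -> float:
    """Distance (um) from the interface to where a solute first falls below
    ``threshold`` (NaN if it never does)."""
    z = profile.depth_um
    s = profile.concentrations[solute]
    # walk from the interface (last node) toward the substratum
    for i in range(len(z) - 1, 0, -1):
        hi, lo = s[i], s[i - 1]
        if hi >= threshold > lo:
            frac = (hi - threshold) / (hi - lo)
            z_cross = z[i] - frac * (z[i] - z[i - 1])
            return float(z[-1] - z_cross)
        if hi < threshold:
            return float(z[-1] - z[i])
    if s[0] < threshold:
        return float(z[-1] - z[0])
    return float("nan")
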