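"""Synthetic inputs with the statistical structure each analysis stage
assumes.

Three generators mirror the three experimental data streams:

* noisy NADH-depletion progress curves simulated from the five-constant
  kinetic scheme at the assay's starting substrate concentrations;
* idealised Calpha ring assemblies (stacked 5-fold rings with a configured
  twist and rise) and conformational ensembles with a two-state flexible
  loop of known occupancy and displacement;
* particle-count tables with a known linear filament-fraction trend plus
  binomial sampling noise.

Every generator is deterministic given (config, seed) and returns a truth
record alongside its data, so recovery tests can compare estimates to the
generating parameters.  Synthetic structures are idealised rings, not real
protein folds: the geometry statistics consume only topology and
coordinates, so a real fold would add no test power.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .kinetics import ProgressCurve, RateConstants, derive_steady_state, simulate_progress
from .structures import Ensemble, StructureModel
from .time_resolved import ParticleCountTable

__all__ = [
    "KineticsConfig",
    "RingConfig",
    "LoopEnsembleConfig",
    "CountsConfig",
    "gen_progress_curves",
    "gen_ring_assembly",
    "gen_loop_ensemble",
    "gen_particle_counts",
    "write_truth",
]


def write_truth(truth: dict, path) -> None:
    """Write a generator truth record as JSON."""
    Path(path).write_text(json.dumps(truth, indent=2, default=float))


# ---------------------------------------------------------------------------
# Kinetics
# ---------------------------------------------------------------------------


@dataclass
class KineticsConfig:
    """Progress-curve generator settings.

    Defaults reproduce the assay conditions: three starting substrate
    concentrations of 750/375/188 uM with n = 8 replicates, 5-minute time
    courses, enzyme at 2.4 uM active sites (0.1 mg/mL at ~42 kDa monomer),
    and rate constants giving kcat = 3.125 /s and KM ~ 59 uM — in the range
    measured for the decameric enzyme.  Noise is additive i.i.d. Gaussian
    per point with SD ``noise_frac`` of the full-scale signal S0.
    """

    seed: int
    rates: RateConstants = field(
        default_factory=lambda: RateConstants(1e6, 150.0, 10.0, 1.0, 5.0)
    )
    e0: float = 2.4e-6
    s0_list: tuple = (750e-6, 375e-6, 188e-6)
    n_replicates: int = 8
    noise_frac: float = 0.01
    t_end: float = 300.0
    n_points: int = 61


def gen_progress_curves(
    config: KineticsConfig,
) -> tuple[list[list[ProgressCurve]], dict]:
    """Simulate replicate progress curves at each S0.

    Returns one replicate list per starting concentration, plus a truth
    record holding the generating rate constants and the derived
    steady-state parameters.
    """
    if config.noise_frac < 0:
        raise ValueError("noise_frac must be >= 0")
    rng = np.random.default_rng(config.seed)
    times = np.linspace(0.0, config.t_end, config.n_points)
    groups = []
    for s0 in config.s0_list:
        clean, _ = simulate_progress(config.rates, config.e0, s0, times)
        reps = []
        for r in range(config.n_replicates):
            noise = rng.normal(0.0, config.noise_frac * s0, size=times.shape)
            reps.append(
                ProgressCurve(
                    time=times.copy(),
                    trace=clean.trace + noise,
                    s0=s0,
                    e0=config.e0,
                    units="molar",
                    replicate=r + 1,
                    condition=f"S0={s0 * 1e6:g}uM",
                )
            )
        groups.append(reps)
    mm = derive_steady_state(config.rates)
    truth = {
        "rates": asdict(config.rates),
        "kcat": mm.kcat,
        "KM": mm.KM,
        "kcat_over_KM": mm.kcat_over_KM,
        "e0": config.e0,
        "s0_list": list(config.s0_list),
        "noise_frac": config.noise_frac,
        "seed": config.seed,
    }
    return groups, truth


def write_progress_table(groups: list[list[ProgressCurve]], path) -> None:
    """Write replicate curves as a delimited table (columns time_s, signal,
    replicate, condition, S0_M, E0_M)."""
    rows = []
    for reps in groups:
        for c in reps:
            rows.append(
                pd.DataFrame(
                    {
                        "time_s": c.time,
                        "signal": c.trace,
                        "replicate": c.replicate,
                        "condition": c.condition,
                        "S0_M": c.s0,
                        "E0_M": c.e0,
                    }
                )
            )
    pd.concat(rows, ignore_index=True).to_csv(path, index=False)


def read_progress_table(path, units: str = "molar") -> list[list[ProgressCurve]]:
    """Read a progress-curve table back into replicate groups by condition."""
    df = pd.read_csv(path)
    groups = []
    for cond, sub in df.groupby("condition", sort=False):
        reps = []
        for rep, rsub in sub.groupby("replicate", sort=True):
            rsub = rsub.sort_values("time_s")
            reps.append(
                ProgressCurve(
                    time=rsub["time_s"].to_numpy(),
                    trace=rsub["signal"].to_numpy(),
                    s0=float(rsub["S0_M"].iloc[0]),
                    e0=float(rsub["E0_M"].iloc[0]),
                    units=units,
                    replicate=rep,
                    condition=str(cond),
                )
            )
        groups.append(reps)
    return groups


# ---------------------------------------------------------------------------
# Ring assemblies and loop ensembles
# ---------------------------------------------------------------------------

_RING1 = "ABCDE"
_RING2 = "FGHIJ"


@dataclass
class RingConfig:
    """Idealised ring-assembly generator settings.

    Chains are Calpha-only helical arcs placed on a circle of ``radius``;
    a second stacked ring (when ``two_rings``) is rotated by ``twist_deg``
    and translated by ``rise`` along the ring axis, emulating one ring of a
    filament related to the next by a screw operation under 5-fold
    symmetry.
    """

    chains_per_ring: int = 5
    n_residues: int = 24
    radius: float = 45.0
    twist_deg: float = 26.0
    rise: float = 40.0
    two_rings: bool = True
    loop_range: tuple = (9, 14)
    jitter: float = 0.0
    seed: int | None = None


def _rot_z(deg: float) -> np.ndarray:
    a = np.radians(deg)
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def _chain_template(n_residues: int, radius: float) -> np.ndarray:
    """A short helical Calpha arc centred at (radius, 0, 0)."""
    t = np.arange(n_residues, dtype=float)
    local = np.column_stack(
        [
            4.0 * np.cos(0.7 * t),
            4.0 * np.sin(0.7 * t),
            1.5 * (t - t.mean()),
        ]
    )
    local[:, 0] += radius
    return local


def _assemble(config: RingConfig) -> tuple[StructureModel, np.ndarray]:
    """Build the ring model; also return per-atom radial unit vectors
    (the loop displacement direction)."""
    m = config.chains_per_ring
    template = _chain_template(config.n_residues, config.radius)
    step = 360.0 / m
    chain_ids = []
    coords = []
    ring_names = [_RING1, _RING2] if config.two_rings else [_RING1]
    for ring_i, names in enumerate(ring_names):
        extra = _rot_z(config.twist_deg) if ring_i == 1 else np.eye(3)
        zoff = np.array([0.0, 0.0, config.rise * ring_i])
        for k in range(m):
            R = extra @ _rot_z(step * k)
            xyz = template @ R.T + zoff
            coords.append(xyz)
            chain_ids.extend([names[k]] * config.n_residues)
    coords = np.vstack(coords)
    n = len(chain_ids)
    resid = np.tile(np.arange(1, config.n_residues + 1), n // config.n_residues)
    model = StructureModel(
        chain=np.array(chain_ids),
        resid=resid,
        resname=np.array(["GLY"] * n),
        atom_name=np.array(["CA"] * n),
        element=np.array(["C"] * n),
        coords=coords,
        occupancy=np.ones(n),
        name="synthetic_ring",
    )
    radial = coords.copy()
    radial[:, 2] = 0.0
    norms = np.linalg.norm(radial, axis=1, keepdims=True)
    radial = radial / np.where(norms > 0, norms, 1.0)
    return model, radial


def gen_ring_assembly(config: RingConfig) -> tuple[StructureModel, dict]:
    """One or two stacked n-fold Calpha rings with known twist and rise."""
    if config.chains_per_ring < 3:
        raise ValueError("need at least 3 chains per ring")
    model, _ = _assemble(config)
    if config.jitter > 0:
        rng = np.random.default_rng(config.seed)
        model = model.with_coords(
            model.coords + rng.normal(0.0, config.jitter, model.coords.shape)
        )
    truth = {
        "twist_deg": config.twist_deg,
        "rise": config.rise,
        "chains_per_ring": config.chains_per_ring,
        "ring1_chains": list(_RING1[: config.chains_per_ring]),
        "ring2_chains": list(_RING2[: config.chains_per_ring])
        if config.two_rings
        else [],
    }
    return model, truth


@dataclass
class LoopEnsembleConfig:
    """Two-state loop ensemble generator settings.

    Each conformation assigns every chain's loop (residues ``loop_range``)
    to an open or closed state; open loops are displaced radially outward
    by ``displacement``.  With ``exact_occupancy`` the number of open
    instances per chain equals round(occupancy * n_conformations) exactly
    (seeded shuffle of which conformations are open), so the empirical
    open fraction matches the configured one; otherwise states are i.i.d.
    Bernoulli draws.  Defaults give a loop RMSF of ~10.5 A at the tip,
    emulating the >10 A fluctuations seen for the gating loop of the
    turnover-filament ensemble; ``n_conformations`` matches the 20-replica
    ensembles this pipeline consumes.
    """

    seed: int
    n_conformations: int = 20
    occupancy: float = 0.5
    displacement: float = 21.0
    jitter: float = 0.15
    exact_occupancy: bool = True
    ring: RingConfig = field(
        default_factory=lambda: RingConfig(twist_deg=26.0, rise=40.0)
    )


def gen_loop_ensemble(config: LoopEnsembleConfig) -> tuple[Ensemble, dict]:
    """Ensemble of a ring assembly with a two-state flexible loop.

    The truth record stores, per loop residue, the expected RMSF
    sqrt(3*jitter^2 + p(1-p)*d^2), and the closed/open minimum distances
    for a probe residue pair (loop tip vs. a rigid residue of the same
    chain) together with their mixture weights.
    """
    if not 0.0 <= config.occupancy <= 1.0:
        raise ValueError("occupancy must be in [0, 1]")
    if config.n_conformations < 2:
        raise ValueError("need at least 2 conformations")
    base, radial = _assemble(config.ring)
    rng = np.random.default_rng(config.seed)
    n_conf = config.n_conformations
    p = config.occupancy
    lo, hi = config.ring.loop_range
    loop_mask = (base.resid >= lo) & (base.resid <= hi)

    chains = base.chains
    open_states = np.zeros((n_conf, len(chains)), dtype=bool)
    for j in range(len(chains)):
        if config.exact_occupancy:
            n_open = int(round(p * n_conf))
            states = np.zeros(n_conf, bool)
            states[:n_open] = True
            rng.shuffle(states)
        else:
            states = rng.random(n_conf) < p
        open_states[:, j] = states

    coords = np.empty((n_conf, base.n_atoms, 3))
    for m in range(n_conf):
        xyz = base.coords.copy()
        for j, c in enumerate(chains):
            if open_states[m, j]:
                sel = loop_mask & (base.chain == c)
                xyz[sel] += config.displacement * radial[sel]
        if config.jitter > 0:
            xyz += rng.normal(0.0, config.jitter, xyz.shape)
        coords[m] = xyz
    ensemble = Ensemble(topology=base, coords=coords, label="synthetic_loop")

    # probe pair: loop tip vs. a rigid residue of the same chain
    tip = (lo + hi) // 2
    probe_rigid = config.ring.n_residues - 4
    from scipy.spatial.distance import cdist  # local import avoids cycle cost

    c0 = chains[0]
    tip_idx = np.flatnonzero((base.chain == c0) & (base.resid == tip))
    rig_idx = np.flatnonzero((base.chain == c0) & (base.resid == probe_rigid))
    d_closed = float(cdist(base.coords[tip_idx], base.coords[rig_idx]).min())
    open_xyz = base.coords[tip_idx] + config.displacement * radial[tip_idx]
    d_open = float(cdist(open_xyz, base.coords[rig_idx]).min())

    base_var = 3.0 * config.jitter**2
    p_emp = open_states.mean() if config.exact_occupancy else p
    loop_resids = list(range(lo, hi + 1))
    expected_rmsf = {
        r: float(
            np.sqrt(base_var + p_emp * (1 - p_emp) * config.displacement**2)
        )
        for r in loop_resids
    }
    truth = {
        "occupancy": p,
        "empirical_occupancy": float(open_states.mean()),
        "displacement": config.displacement,
        "jitter": config.jitter,
        "loop_range": [lo, hi],
        "expected_loop_rmsf": expected_rmsf,
        "expected_baseline_rmsf": float(np.sqrt(base_var)),
        "probe_pair": {
            "residueA": tip,
            "residueB": probe_rigid,
            "d_closed": d_closed,
            "d_open": d_open,
            "weight_open": float(p_emp),
        },
        "seed": config.seed,
    }
    return ensemble, truth


# ---------------------------------------------------------------------------
# Particle counts
# ---------------------------------------------------------------------------


@dataclass
class CountsConfig:
    """Particle-count generator settings.

    Default quench times span 57-517 s (five datasets); the true filament
    fraction follows intercept + slope*t, rising from ~0.10 to ~0.50 over
    the series — the plateau observed for the filament fraction at the
    standard enzyme concentration.  Filament counts are binomial draws
    from the true fraction at each time; unassigned picks are drawn
    independently and never enter the fraction denominator.
    """

    seed: int
    times: tuple = (57.0, 172.0, 287.0, 402.0, 517.0)
    slope: float = 8.7e-4
    intercept: float = 0.05
    totals: int | tuple = 10000
    unassigned_frac: float = 0.3


def gen_particle_counts(config: CountsConfig) -> tuple[ParticleCountTable, dict]:
    """Binomial particle-count table with a linear true fraction."""
    times = np.asarray(config.times, float)
    f_true = config.intercept + config.slope * times
    if np.any((f_true < 0) | (f_true > 1)):
        raise ValueError("true fraction outside [0, 1] at some configured time")
    totals = (
        np.full(len(times), config.totals, int)
        if np.isscalar(config.totals)
        else np.asarray(config.totals, int)
    )
    rng = np.random.default_rng(config.seed)
    filament = rng.binomial(totals, f_true)
    decamer = totals - filament
    unassigned = rng.binomial(totals, config.unassigned_frac)
    df = pd.DataFrame(
        {
            "dataset_id": [f"tr{i + 1}" for i in range(len(times))],
            "time_s": times,
            "n_decamer": decamer,
            "n_filament": filament,
            "n_unassigned": unassigned,
        }
    )
    truth = {
        "slope": config.slope,
        "intercept": config.intercept,
        "times": times.tolist(),
        "true_fractions": f_true.tolist(),
        "totals": totals.tolist(),
        "seed": config.seed,
    }
    return ParticleCountTable(data=df, mode="independent"), truth
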