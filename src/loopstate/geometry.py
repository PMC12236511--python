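"""Geometry statistics on structures and conformational ensembles.

Implements the measurements used to compare oligomeric states of a
ring-forming enzyme: least-squares superposition and rotation-angle
extraction, filament twist/rise between stacked rings, rotation about the
pentamer-pentamer interface, per-monomer domain hinge ("crimping")
rotation, per-residue RMSF of an ensemble, minimum inter-residue distance
distributions with KDE/histogram summaries, and Calpha distance-difference
matrices between two conformational states.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist
from scipy.stats import gaussian_kde

from .structures import AtomSelection, Ensemble, StructureModel, StructureError

__all__ = [
    "RigidTransform",
    "RMSFProfile",
    "DistanceDistribution",
    "DistanceDifferenceMatrix",
    "superpose",
    "rotation_angle",
    "filament_twist",
    "interpentamer_rotation",
    "domain_rotation",
    "rmsf",
    "min_distance_distribution",
    "kde_density",
    "histogram",
    "ca_distance_difference",
    "cross_pentamer_ca_distance",
]


@dataclass
class RigidTransform:
    """Proper rotation + translation mapping mobile onto reference.

    ``apply(x) = x @ rotation.T + translation``.  ``angle`` (degrees, in
    [0, 180]) and ``axis`` (unit vector) describe the rotation;
    ``rmsd`` is the post-superposition RMSD in angstroms.
    """

    rotation: np.ndarray
    translation: np.ndarray
    angle: float
    axis: np.ndarray
    rmsd: float

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, float)
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-8) or not np.isclose(
            np.linalg.det(R), 1.0, atol=1e-8
        ):
            raise StructureError("rotation must be proper orthonormal")

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords, float) @ self.rotation.T + self.translation


def _angle_axis(R: np.ndarray) -> tuple[float, np.ndarray]:
    """Rotation angle (deg, [0,180]) and unit axis of a rotation matrix."""
    cos = np.clip((np.trace(R) - 1.0) / 2.0, -1.0, 1.0)
    angle = float(np.degrees(np.arccos(cos)))
    # axis from the antisymmetric part; fall back to the +1 eigenvector
    v = np.array([R[2, 1] - R[1, 2], R[0, 2] - R[2, 0], R[1, 0] - R[0, 1]])
    norm = np.linalg.norm(v)
    if norm > 1e-12:
        axis = v / norm
    else:
        w, V = np.linalg.eigh((R + R.T) / 2)
        axis = V[:, np.argmax(w)]
        axis = axis / np.linalg.norm(axis)
    return angle, axis


def superpose(mobile: np.ndarray, reference: np.ndarray) -> RigidTransform:
    """Least-squares (Kabsch) superposition of paired point sets.

    Finds the proper rotation R and translation t minimising
    ``|| R x_mobile + t - x_reference ||``; a reflection is never returned.
    """
    P = np.asarray(mobile, float)
    Q = np.asarray(reference, float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise StructureError("point sets must be (n, 3) with equal n")
    if P.shape[0] < 3:
        raise StructureError("need at least 3 points")
    pc, qc = P.mean(axis=0), Q.mean(axis=0)
    P0, Q0 = P - pc, Q - qc
    if np.linalg.matrix_rank(P0, tol=1e-9) < 2:
        raise StructureError("points are collinear")
    H = P0.T @ Q0
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = qc - R @ pc
    rmsd = float(np.sqrt(np.mean(np.sum((P0 @ R.T - Q0) ** 2, axis=1))))
    angle, axis = _angle_axis(R)
    return RigidTransform(rotation=R, translation=t, angle=angle, axis=axis,
                          rmsd=rmsd)


def rotation_angle(transform: RigidTransform, modulo_symmetry: int = 1) -> float:
    """Rotation angle reduced modulo an n-fold symmetry.

    The angle about the rotation axis is mapped modulo 360/n into
    [0, 180/n] degrees; e.g. under 5-fold symmetry a 46 degree rotation is
    equivalent to 26 degrees.
    """
    if modulo_symmetry < 1:
        raise StructureError("symmetry order must be >= 1")
    period = 360.0 / modulo_symmetry
    a = transform.angle % period
    return float(min(a, period - a))


def _per_chain_coords(
    model: StructureModel, selection: AtomSelection
) -> dict[str, np.ndarray]:
    idx = selection.resolve(model)
    out: dict[str, list[int]] = {}
    for i in idx:
        out.setdefault(str(model.chain[i]), []).append(i)
    return {c: model.coords[ii] for c, ii in out.items()}


def filament_twist(
    model: StructureModel,
    ringA: AtomSelection,
    ringB: AtomSelection,
    symmetry: int = 5,
    chain_map: dict[str, str] | None = None,
) -> tuple[float, float]:
    """Twist (degrees) and rise (angstroms) between two stacked rings.

    Ring A is superposed onto ring B under a chain correspondence; when no
    explicit ``chain_map`` is given the cyclic assignment (in selection
    chain order) minimising the post-superposition RMSD is used.  The
    rotation angle is reduced modulo 360/symmetry into [0, 180/symmetry]
    (for 5-fold rings: [0, 36] degrees); rise is the centroid displacement
    along the rotation axis.
    """
    a_chains = _per_chain_coords(model, ringA)
    b_chains = _per_chain_coords(model, ringB)
    ca, cb = list(a_chains), list(b_chains)
    if chain_map is not None:
        maps = [chain_map]
    else:
        if len(ca) != len(cb):
            raise StructureError("rings have different chain counts")
        maps = [
            {ca[i]: cb[(i + j) % len(cb)] for i in range(len(ca))}
            for j in range(len(cb))
        ]
    best: tuple[RigidTransform, dict] | None = None
    for m in maps:
        try:
            P = np.vstack([a_chains[c] for c in m])
            Q = np.vstack([b_chains[m[c]] for c in m])
        except KeyError as e:
            raise StructureError(f"chain correspondence mismatch: {e}")
        if P.shape != Q.shape:
            raise StructureError("chain correspondence gives unequal atom counts")
        tr = superpose(P, Q)
        if best is None or tr.rmsd < best[0].rmsd:
            best = (tr, m)
    tr, used_map = best
    twist = rotation_angle(tr, modulo_symmetry=symmetry)
    centroid_shift = np.vstack(list(b_chains.values())).mean(axis=0) - np.vstack(
        list(a_chains.values())
    ).mean(axis=0)
    rise = float(abs(centroid_shift @ tr.axis))
    return twist, rise


def interpentamer_rotation(
    modelA: StructureModel,
    modelB: StructureModel,
    anchor: AtomSelection,
    probe: AtomSelection,
) -> float:
    """Rotation (degrees) of the probe ring between two models after
    anchoring on the other ring.

    Model B is superposed onto model A using the anchor selection; the
    residual transform between the probe selections then isolates the
    relative ring rotation.  No symmetry reduction is applied — the motion
    of interest is a fraction of a degree.
    """
    ia, ib = anchor.resolve(modelA), anchor.resolve(modelB)
    pa, pb = probe.resolve(modelA), probe.resolve(modelB)
    if len(ia) != len(ib) or len(pa) != len(pb):
        raise StructureError("selections resolve to unequal atom counts")
    tr_anchor = superpose(modelB.coords[ib], modelA.coords[ia])
    probe_b_aligned = tr_anchor.apply(modelB.coords[pb])
    tr_probe = superpose(modelA.coords[pa], probe_b_aligned)
    return tr_probe.angle


def domain_rotation(
    modelA: StructureModel,
    modelB: StructureModel,
    fixed_domain: AtomSelection,
    mobile_domain: AtomSelection,
) -> float:
    """Hinge rotation (degrees) of a mobile domain between two models,
    after aligning on the fixed domain.  Measures per-monomer "crimping"
    between e.g. catalytic and beta-grasp domains."""
    return interpentamer_rotation(modelA, modelB, fixed_domain, mobile_domain)


@dataclass
class RMSFProfile:
    """Per-atom RMSF keyed by (chain, residue)."""

    keys: list  # (chain, resid) per reported atom
    values: np.ndarray  # A
    atom_name: str = "CA"

    def as_dict(self) -> dict:
        return dict(zip(self.keys, map(float, self.values)))

    def max(self) -> float:
        return float(self.values.max())


def rmsf(
    ensemble: Ensemble,
    align_on: AtomSelection,
    report_on: AtomSelection,
) -> RMSFProfile:
    """Per-residue RMSF after iterative mean-structure alignment.

    Each conformation is superposed on the evolving ensemble-mean structure
    using the alignment selection (2 iterations: align to conformation 1,
    recompute the mean, re-align to the mean).  RMSF of a reported atom is
    the root-mean-square displacement from its mean position across
    conformations.
    """
    if ensemble.n_conformations < 2:
        raise StructureError("RMSF needs >= 2 conformations")
    topo = ensemble.topology
    ai = align_on.resolve(topo)
    ri = report_on.resolve(topo)
    coords = ensemble.coords.copy()
    ref = coords[0, ai]
    for _ in range(2):
        for m in range(coords.shape[0]):
            tr = superpose(coords[m, ai], ref)
            coords[m] = tr.apply(coords[m])
        ref = coords[:, ai].mean(axis=0)
    mean_pos = coords[:, ri].mean(axis=0)
    disp2 = np.sum((coords[:, ri] - mean_pos) ** 2, axis=2)
    values = np.sqrt(disp2.mean(axis=0))
    keys = [(str(topo.chain[i]), int(topo.resid[i])) for i in ri]
    names = set(topo.atom_name[ri])
    return RMSFProfile(keys=keys, values=values,
                       atom_name=names.pop() if len(names) == 1 else "mixed")


@dataclass
class DistanceDistribution:
    """Minimum inter-residue distances over an ensemble, with summaries."""

    residue_pair: tuple
    samples: np.ndarray  # (n_conformations, n_chains)
    chains: list
    kde_grid: np.ndarray | None = None
    kde_density: np.ndarray | None = None
    hist_counts: np.ndarray | None = None
    hist_edges: np.ndarray | None = None
    pairing: str = "intra-chain"

    @property
    def flat(self) -> np.ndarray:
        return self.samples.ravel()


def min_distance_distribution(
    ensemble: Ensemble,
    residueA: int,
    residueB: int,
    per_chain: bool = True,
    exclude_hydrogens: bool = True,
    chain_map: dict[str, str] | None = None,
    bins: int = 150,
    bandwidth_adjust: float = 1.0,
) -> DistanceDistribution:
    """Minimum interatomic distance between two residues, per conformation
    and per chain.

    For each conformation and each analysed chain, the minimum over all
    atom pairs of the residue-residue interatomic distance is recorded (a
    10-chain ensemble yields 10 distances per conformation).  Pairing is
    intra-chain by default; a ``chain_map`` pairs residue A in one chain
    with residue B in another (e.g. across a ring interface).  KDE
    (Scott bandwidth times ``bandwidth_adjust``) and a ``bins``-bin
    histogram of the pooled samples are attached when computable.
    """
    topo = ensemble.topology
    chains = topo.chains if per_chain else topo.chains[:1]
    if chain_map is None:
        pairs = [(c, c) for c in chains]
        pairing = "intra-chain"
    else:
        pairs = list(chain_map.items())
        pairing = "cross-chain"
    idx_pairs = []
    for ca, cb in pairs:
        ia = np.flatnonzero(
            topo.mask(chains=ca, residues=residueA,
                      exclude_hydrogens=exclude_hydrogens))
        ib = np.flatnonzero(
            topo.mask(chains=cb, residues=residueB,
                      exclude_hydrogens=exclude_hydrogens))
        if ia.size == 0:
            raise StructureError(f"residue {residueA} missing in chain {ca}")
        if ib.size == 0:
            raise StructureError(f"residue {residueB} missing in chain {cb}")
        idx_pairs.append((ia, ib))
    n_conf = ensemble.n_conformations
    samples = np.empty((n_conf, len(pairs)))
    for m in range(n_conf):
        xyz = ensemble.coords[m]
        for j, (ia, ib) in enumerate(idx_pairs):
            samples[m, j] = cdist(xyz[ia], xyz[ib]).min()
    dist = DistanceDistribution(
        residue_pair=(residueA, residueB),
        samples=samples,
        chains=[p for p in pairs],
        pairing=pairing,
    )
    flat = samples.ravel()
    dist.hist_counts, dist.hist_edges = histogram(flat, bins=bins)
    if flat.size >= 2 and flat.std() > 0:
        dist.kde_grid, dist.kde_density = kde_density(
            flat, bandwidth_adjust=bandwidth_adjust)
    return dist


def kde_density(
    samples: np.ndarray,
    bandwidth_adjust: float = 1.0,
    grid_points: int = 512,
) -> tuple[np.ndarray, np.ndarray]:
    """Gaussian KDE on a 1-D sample.

    The base bandwidth follows Scott's rule and is multiplied by
    ``bandwidth_adjust``; the density is evaluated on ``grid_points``
    points spanning [min - 3h, max + 3h] so it integrates to ~1.
    """
    x = np.asarray(samples, float).ravel()
    if x.size < 2 or x.std() == 0:
        raise StructureError(
            "KDE needs >= 2 samples with nonzero variance; use a histogram")
    kde = gaussian_kde(x, bw_method="scott")
    kde.set_bandwidth(kde.factor * bandwidth_adjust)
    h = kde.factor * x.std(ddof=1)
    grid = np.linspace(x.min() - 3 * h, x.max() + 3 * h, grid_points)
    return grid, kde(grid)


def histogram(samples: np.ndarray, bins: int = 150
              ) -> tuple[np.ndarray, np.ndarray]:
    """Equal-width histogram over [min, max]; the right-most edge is
    inclusive, so counts always sum to the sample count."""
    x = np.asarray(samples, float).ravel()
    if x.size < 1:
        raise StructureError("histogram needs at least 1 sample")
    # pad (near-)constant samples: equal-width bins need a finite range
    if np.ptp(x) <= np.abs(x).max() * 1e-12:
        counts, edges = np.histogram(x, bins=bins,
                                     range=(x.min() - 0.5, x.max() + 0.5))
    else:
        counts, edges = np.histogram(x, bins=bins)
    return counts, edges


@dataclass
class DistanceDifferenceMatrix:
    """Calpha distance differences (model A minus model B) for one chain."""

    residues: np.ndarray
    matrix: np.ndarray  # (n, n) in A
    chain: str
    exclusions: list = field(default_factory=list)
    max_pair: tuple = ()  # (resid_i, resid_j, difference)


def ca_distance_difference(
    modelA: StructureModel,
    modelB: StructureModel,
    chain: str,
    exclusions: list[tuple[int, int]] | None = None,
) -> DistanceDifferenceMatrix:
    """D(i,j) = |CaA_i - CaA_j| - |CaB_i - CaB_j| for one chain.

    Residue ranges in ``exclusions`` (inclusive) are dropped before the
    comparison — e.g. a mobile loop whose heterogeneity would otherwise
    dominate.  The residue sets remaining in both models must agree.  The
    matrix is symmetric with a zero diagonal and is invariant to rigid
    transforms of either model; the (i, j) pair with the largest absolute
    difference is reported.
    """
    exclusions = exclusions or []

    def _ca(model: StructureModel) -> tuple[np.ndarray, np.ndarray]:
        m = model.mask(chains=chain, atom_names="CA")
        idx = np.flatnonzero(m)
        if idx.size == 0:
            raise StructureError(f"chain {chain} has no CA atoms")
        resid = model.resid[idx]
        keep = np.ones(idx.size, bool)
        for lo, hi in exclusions:
            keep &= ~((resid >= lo) & (resid <= hi))
        order = np.argsort(resid[keep], kind="stable")
        return resid[keep][order], model.coords[idx[keep]][order]

    ra, xa = _ca(modelA)
    rb, xb = _ca(modelB)
    if not np.array_equal(ra, rb):
        diff = sorted(set(ra.tolist()) ^ set(rb.tolist()))
        raise StructureError(
            f"residue sets differ after exclusions, symmetric difference {diff}")
    da = cdist(xa, xa)
    db = cdist(xb, xb)
    D = da - db
    iu = np.triu_indices(len(ra), k=1)
    kmax = np.argmax(np.abs(D[iu]))
    max_pair = (int(ra[iu[0][kmax]]), int(ra[iu[1][kmax]]),
                float(D[iu][kmax]))
    return DistanceDifferenceMatrix(
        residues=ra, matrix=D, chain=chain, exclusions=list(exclusions),
        max_pair=max_pair)


def cross_pentamer_ca_distance(
    model: StructureModel,
    residueA: tuple[str, int],
    residueB: tuple[str, int],
) -> float:
    """Single Ca-Ca distance between (chain, residue) pairs, in angstroms.

    The two chains may differ (e.g. residue 74 of one monomer against
    residue 263 of the adjacent monomer across a ring) or coincide; a
    distance *change* between two models is obtained by applying this to
    each model and subtracting.
    """
    out = []
    for chain, resid in (residueA, residueB):
        idx = np.flatnonzero(
            model.mask(chains=chain, residues=resid, atom_names="CA"))
        if idx.size == 0:
            raise StructureError(f"no CA for residue {resid} in chain {chain}")
        out.append(model.coords[idx[0]])
    return float(np.linalg.norm(out[0] - out[1]))
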