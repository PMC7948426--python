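"""Synthetic fixtures with known ground truth for every pipeline stage.

Real inputs to the pipeline (homology models of receptors, superposed crystal
structures, plate-reader tables) cannot ship with the package, so this module
generates structurally analogous stand-ins whose ground truth is known by
construction:

* :func:`make_bundle` — a seven-helix-bundle-like Cα scaffold (ring of
  helices plus a central column so the interior is filled) with ionizable
  residues planted at controlled signed depths relative to the bundle's own
  alpha-shape surface, and His residues planted above/below the z = 0
  midplane;
* :func:`make_ensemble` — jittered superposed copies of a point scaffold
  containing planted spatially conserved sites (and optional Na+ ions) plus
  scattered decoys, for consensus clustering;
* :func:`simulate_titration` — 4PL-shaped pH-response curves with Gaussian
  noise;
* :func:`simulate_dvp` — variant fluorescence tables with lognormal noise
  around known fold changes.

Every generator is a pure function of its spec: the same spec and seed yield
byte-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .phinder_core import (
    CHARGE_GROUP_ATOMS,
    SurfaceMesh,
    build_surface,
    classify_burial,
    residue_depth,
)
from .structure_io import AtomRecord, StructureModel

#: representative planted depths per burial class, ≥1.5 Å from both class
#: boundaries (-3.0 and +1.05) even after the 0.2 Å placement tolerance
CLASS_TARGET_DEPTHS = {"core": -5.0, "margin": -0.75, "exposed": 3.0}


@dataclass
class PlantedSite:
    """One ionizable residue to plant at a known signed depth."""

    residue_name: str  # ASP/GLU/HIS/LYS/ARG
    target: str | float  # burial class name or signed depth in Å
    helix: int  # host helix index (0-based; ring helices)
    axial_fraction: float = 0.5  # 0 = bottom of the helix, 1 = top

    @property
    def target_depth(self) -> float:
        if isinstance(self.target, str):
            return CLASS_TARGET_DEPTHS[self.target]
        return float(self.target)


@dataclass
class BundleSpec:
    """Geometry and planted content of a synthetic helical bundle."""

    seed: int
    n_helices: int = 7
    helix_radius: float = 2.3  # Å, radius of each helical curve
    bundle_radius: float = 8.0  # Å, ring radius of helix axes
    residues_per_helix: int = 30
    rise_per_residue: float = 1.5  # Å along z
    turn_per_residue_deg: float = 100.0
    planted_sites: list[PlantedSite] = field(default_factory=list)
    planted_ehis: list[bool] = field(default_factory=list)  # True = above plane


@dataclass
class EnsembleSpec:
    """Superposed ensemble with planted consensus sites and decoys."""

    seed: int
    n_structures: int = 8
    genes: list[str] = field(default_factory=list)  # one label per structure
    consensus_sites: np.ndarray = field(
        default_factory=lambda: np.array([[0.0, 0.0, 0.0]])
    )
    jitter_sd: float = 0.3  # Å, positional noise per structure
    decoy_rate: float = 3.0  # expected decoy sites per structure
    decoy_min_separation: float = 7.5  # ≥5x the 1.5 Å clustering cutoff
    box_half_width: float = 25.0  # decoys scattered in [-w, w]^3
    na_site: np.ndarray | None = None  # optional planted Na+ consensus site
    na_structures: list[int] | None = None  # indices carrying an Na+ ion

    def __post_init__(self):
        if self.jitter_sd < 0:
            raise ValueError("jitter_sd must be non-negative")
        self.consensus_sites = np.atleast_2d(np.asarray(self.consensus_sites, float))
        if len(self.consensus_sites) < 1:
            raise ValueError("at least one consensus site required")
        if not self.genes:
            self.genes = [f"GENE{i + 1}" for i in range(self.n_structures)]
        if len(self.genes) != self.n_structures:
            raise ValueError("genes must list one gene label per structure")


@dataclass
class TitrationSpec:
    """4PL curve shape, sampling grid and noise model."""

    seed: int
    bottom: float = 0.0
    top: float = 1.0
    ph50: float = 6.8
    hill_slope: float = 1.5
    ph_grid: np.ndarray = field(default_factory=lambda: np.linspace(5.0, 8.0, 10))
    noise_sd_frac: float = 0.05  # Gaussian SD as a fraction of (top - bottom)
    replicates: int = 1

    def __post_init__(self):
        if self.top <= self.bottom:
            raise ValueError("top must exceed bottom")
        if self.noise_sd_frac < 0:
            raise ValueError("noise_sd_frac must be non-negative")
        self.ph_grid = np.asarray(self.ph_grid, float)


def _helix_points(spec: BundleSpec, helix: int) -> np.ndarray:
    """Cα positions of one ring helix of the bundle."""
    theta = 2.0 * math.pi * helix / spec.n_helices
    cx = spec.bundle_radius * math.cos(theta)
    cy = spec.bundle_radius * math.sin(theta)
    omega = math.radians(spec.turn_per_residue_deg)
    height = (spec.residues_per_helix - 1) * spec.rise_per_residue
    pts = []
    for i in range(spec.residues_per_helix):
        phi = omega * i + theta
        pts.append(
            (
                cx + spec.helix_radius * math.cos(phi),
                cy + spec.helix_radius * math.sin(phi),
                -height / 2.0 + i * spec.rise_per_residue,
            )
        )
    return np.array(pts)


def _central_column(spec: BundleSpec) -> np.ndarray:
    """Cα positions filling the central pore (a narrow axial spiral)."""
    height = (spec.residues_per_helix - 1) * spec.rise_per_residue
    n = max(4, int(height / 3.0) + 1)
    pts = []
    for i in range(n):
        phi = 2.0 * i  # radians; spiral avoids exact collinearity
        pts.append(
            (
                0.8 * math.cos(phi),
                0.8 * math.sin(phi),
                -height / 2.0 + i * height / (n - 1),
            )
        )
    return np.array(pts)


def _reference_atoms_for(resname: str, point: np.ndarray) -> list[tuple[str, np.ndarray]]:
    """Side-chain atoms realizing the given charged-group reference point."""
    if resname == "HIS":
        # ND1/NE2 placed symmetrically so their midpoint is the target
        offset = np.array([0.8, 0.0, 0.0])
        return [("ND1", point - offset), ("NE2", point + offset)]
    (atom_name,) = CHARGE_GROUP_ATOMS[resname]
    return [(atom_name, point.copy())]


def _scaffold_model(spec: BundleSpec) -> tuple[StructureModel, dict[int, list[int]]]:
    """Plain-glycine scaffold plus a map helix index -> residue numbers.

    Seeded 0.15 Å Gaussian jitter on every Cα makes distinct seeds produce
    distinct (but equally well-formed) bundles.
    """
    rng = np.random.default_rng(spec.seed)
    atoms: list[AtomRecord] = []
    helix_residues: dict[int, list[int]] = {}
    resnum = 0
    serial = 0
    for h in range(spec.n_helices):
        helix_residues[h] = []
        for pos in _helix_points(spec, h):
            resnum += 1
            serial += 1
            helix_residues[h].append(resnum)
            atoms.append(
                AtomRecord(serial, "CA", "GLY", "A", resnum, " ",
                           pos + rng.normal(scale=0.15, size=3), "C", False)
            )
    for pos in _central_column(spec):
        resnum += 1
        serial += 1
        atoms.append(
            AtomRecord(serial, "CA", "GLY", "A", resnum, " ",
                       pos + rng.normal(scale=0.15, size=3), "C", False)
        )
    return StructureModel(f"bundle_{spec.seed}", f"BUNDLE{spec.seed}", atoms), helix_residues


def _converge_depth(
    start: np.ndarray, target_depth: float, mesh: SurfaceMesh, max_iter: int = 20
) -> tuple[np.ndarray, float]:
    """Move a point radially (in x, y) until its signed depth hits the target.

    The bundle surface is roughly a cylinder around z, so depth responds
    nearly unit-linearly to radial displacement; a damped fixed-point update
    converges in a few iterations.
    """
    point = np.asarray(start, float).copy()
    radial = point[:2].copy()
    r = float(np.linalg.norm(radial))
    direction = radial / r if r > 1e-9 else np.array([1.0, 0.0])
    depth = residue_depth(point, mesh)
    for _ in range(max_iter):
        if abs(depth - target_depth) <= 0.2:
            break
        r = max(0.2, r + (target_depth - depth))
        point = np.array([direction[0] * r, direction[1] * r, point[2]])
        depth = residue_depth(point, mesh)
    if abs(depth - target_depth) > 1.0:
        raise ValueError(
            f"planted depth {target_depth:+.2f} Å infeasible at this position "
            f"(achieved {depth:+.2f} Å)"
        )
    return point, depth


def make_bundle(spec: BundleSpec) -> tuple[StructureModel, pd.DataFrame]:
    """Synthetic helical bundle with planted ionizable residues.

    Returns the structure model and a ground-truth table with one row per
    planted site: residue identity, target and achieved signed depth, burial
    class at the achieved depth, and (for planted His) the above-plane flag.
    Reference atoms are placed iteratively against the bundle's own
    alpha-shape surface, so the recorded depth is a measured quantity, not an
    assumption.
    """
    model, helix_residues = _scaffold_model(spec)
    mesh = build_surface(model)
    by_residue = {key: list(atoms) for key, atoms in model.residues().items()}

    rows = []
    used: set[int] = set()
    serial = max(a.serial for a in model.atoms)

    for site in spec.planted_sites:
        if site.helix not in helix_residues:
            raise ValueError(f"helix index {site.helix} out of range")
        resnums = helix_residues[site.helix]
        idx = int(round(site.axial_fraction * (len(resnums) - 1)))
        # find the nearest unused residue on this helix
        order = sorted(range(len(resnums)), key=lambda i: (abs(i - idx), i))
        resnum = next(
            (resnums[i] for i in order if resnums[i] not in used), None
        )
        if resnum is None:
            raise ValueError(f"helix {site.helix} has no free residues left")
        used.add(resnum)

        ca = by_residue[("A", resnum, " ")][0]
        point, depth = _converge_depth(ca.position, site.target_depth, mesh)
        new_atoms = [
            AtomRecord(
                ca.serial, "CA", site.residue_name, "A", resnum, " ",
                ca.position, "C", False,
            )
        ]
        for name, pos in _reference_atoms_for(site.residue_name, point):
            serial += 1
            element = "N" if name.startswith("N") else "C"
            new_atoms.append(
                AtomRecord(serial, name, site.residue_name, "A", resnum, " ",
                           pos, element, False)
            )
        by_residue[("A", resnum, " ")] = new_atoms
        rows.append(
            {
                "chain": "A",
                "resnum": resnum,
                "resname": site.residue_name,
                "kind": "site",
                "target_depth": site.target_depth,
                "achieved_depth": depth,
                "burial_class": classify_burial(depth),
                "above_plane": None,
            }
        )

    # planted extracellular/intracellular His: rename scaffold residues whose
    # Cα lies clearly above (z > +2) or below (z < -2) the z = 0 midplane
    candidates = sorted(
        (key for key in by_residue if key[1] not in used),
        key=lambda key: -by_residue[key][0].position[2],
    )
    above_pool = [k for k in candidates if by_residue[k][0].position[2] > 2.0]
    below_pool = [k for k in reversed(candidates) if by_residue[k][0].position[2] < -2.0]
    for flag in spec.planted_ehis:
        pool = above_pool if flag else below_pool
        key = pool.pop(0)
        used.add(key[1])
        ca = by_residue[key][0]
        radial = ca.position[:2]
        direction = radial / max(np.linalg.norm(radial), 1e-9)
        ref = np.array(
            [ca.position[0] + 1.5 * direction[0], ca.position[1] + 1.5 * direction[1],
             ca.position[2]]
        )
        new_atoms = [
            AtomRecord(ca.serial, "CA", "HIS", "A", key[1], " ", ca.position, "C", False)
        ]
        for name, pos in _reference_atoms_for("HIS", ref):
            serial += 1
            new_atoms.append(
                AtomRecord(serial, name, "HIS", "A", key[1], " ", pos, "N", False)
            )
        by_residue[key] = new_atoms
        depth = residue_depth(ref, mesh)
        rows.append(
            {
                "chain": "A",
                "resnum": key[1],
                "resname": "HIS",
                "kind": "ehis",
                "target_depth": np.nan,
                "achieved_depth": depth,
                "burial_class": classify_burial(depth),
                "above_plane": bool(ca.position[2] > 0),
            }
        )

    atoms = [a for key in sorted(by_residue) for a in by_residue[key]]
    out = StructureModel(model.structure_id, model.gene_label, atoms)
    truth = pd.DataFrame(
        rows,
        columns=[
            "chain", "resnum", "resname", "kind",
            "target_depth", "achieved_depth", "burial_class", "above_plane",
        ],
    )
    return out, truth


def triad_bundle_spec(seed: int, n_decoys: int = 10) -> BundleSpec:
    """Bundle spec with a buried acidic triad plus exposed ionizable decoys.

    The triad emulates the receptors' shared motif: two Asp planted deep in
    the core on adjacent helices (the DyaD-like pair) and one Glu planted in
    the core of a helix across the bundle and higher up (the apEx-like site).
    Decoys are surface-exposed ionizable residues of mixed type.
    """
    planted = [
        PlantedSite("ASP", "core", helix=0, axial_fraction=0.5),
        PlantedSite("ASP", "core", helix=1, axial_fraction=0.5),
        PlantedSite("GLU", "core", helix=4, axial_fraction=0.8),
    ]
    decoy_types = ["LYS", "ARG", "HIS", "GLU", "ASP"]
    spec = BundleSpec(seed=seed)
    for i in range(n_decoys):
        planted.append(
            PlantedSite(
                decoy_types[i % len(decoy_types)],
                "exposed",
                helix=i % spec.n_helices,
                axial_fraction=0.15 + 0.7 * ((i * 7) % n_decoys) / max(n_decoys - 1, 1),
            )
        )
    spec.planted_sites = planted
    return spec


def make_triad_bundle(
    seed: int, n_decoys: int = 10, apex_dyad_distance: float = 16.0
) -> tuple[StructureModel, pd.DataFrame]:
    """Triad-plus-decoys bundle with the apEx site re-placed at a fixed
    distance from the DyaD midpoint.

    After the generic depth-converged planting, the Glu reference atom is
    moved onto the sphere of radius ``apex_dyad_distance`` around the DyaD
    midpoint, choosing the direction (scanned over elevation angles) whose
    signed depth stays closest to the core target; its achieved depth is
    re-measured and recorded.
    """
    model, truth = make_bundle(triad_bundle_spec(seed, n_decoys))
    mesh = build_surface(model)

    dyad_rows = truth[(truth.resname == "ASP") & (truth.kind == "site")].iloc[:2]
    glu_row = truth[(truth.resname == "GLU") & (truth.kind == "site")].iloc[0]
    by_residue = model.residues()
    dyad_points = []
    for _, row in dyad_rows.iterrows():
        atoms = by_residue[("A", int(row.resnum), " ")]
        dyad_points.append(next(a for a in atoms if a.atom_name == "CG").position)
    dyad_mid = np.mean(dyad_points, axis=0)

    target_depth = CLASS_TARGET_DEPTHS["core"]
    glu_atoms = by_residue[("A", int(glu_row.resnum), " ")]
    cd = next(a for a in glu_atoms if a.atom_name == "CD")
    radial = cd.position - dyad_mid
    radial[2] = 0.0
    radial /= max(np.linalg.norm(radial), 1e-9)

    best_point, best_depth = None, None
    for phi in np.linspace(0.0, math.pi / 2.0, 46):
        direction = math.cos(phi) * radial + math.sin(phi) * np.array([0.0, 0.0, 1.0])
        candidate = dyad_mid + apex_dyad_distance * direction
        depth = residue_depth(candidate, mesh)
        if best_depth is None or abs(depth - target_depth) < abs(best_depth - target_depth):
            best_point, best_depth = candidate, depth
    if abs(best_depth - target_depth) > 1.0:
        raise ValueError("no direction keeps the apEx site in the core at this distance")

    atoms = list(model.atoms)
    idx = atoms.index(cd)
    atoms[idx] = AtomRecord(
        cd.serial, "CD", "GLU", "A", cd.residue_number, " ", best_point, "C", False
    )
    out = StructureModel(model.structure_id, model.gene_label, atoms)
    truth = truth.copy()
    truth.loc[truth.resnum == glu_row.resnum, "achieved_depth"] = best_depth
    truth.loc[truth.resnum == glu_row.resnum, "burial_class"] = classify_burial(best_depth)
    return out, truth


def make_ensemble(
    spec: EnsembleSpec,
) -> tuple[list[StructureModel], pd.DataFrame, dict]:
    """Jittered superposed ensemble with planted consensus sites and decoys.

    Each structure contributes one Asp (CG reference atom) per consensus
    site, displaced by Gaussian jitter, plus Poisson-distributed decoy sites
    scattered uniformly but kept at least ``decoy_min_separation`` from every
    consensus site.  Structures listed in ``na_structures`` also carry one
    Na+ HETATM jittered around ``na_site``.  Returns the models, a manifest
    (structure_id, gene_label) and the ground truth.
    """
    rng = np.random.default_rng(spec.seed)
    models = []
    manifest_rows = []
    decoy_log = []
    for s in range(spec.n_structures):
        gene = spec.genes[s]
        structure_id = f"ens{spec.seed}_s{s}"
        atoms: list[AtomRecord] = []
        serial = 0
        resnum = 0
        positions = [
            site + rng.normal(scale=spec.jitter_sd, size=3)
            for site in spec.consensus_sites
        ]
        n_decoys = int(rng.poisson(spec.decoy_rate))
        placed = 0
        while placed < n_decoys:
            candidate = rng.uniform(-spec.box_half_width, spec.box_half_width, size=3)
            gap = np.min(
                np.linalg.norm(spec.consensus_sites - candidate, axis=1)
            )
            if gap >= spec.decoy_min_separation:
                positions.append(candidate)
                decoy_log.append((structure_id, candidate))
                placed += 1
        for pos in positions:
            resnum += 1
            serial += 1
            atoms.append(
                AtomRecord(serial, "CA", "ASP", "A", resnum, " ",
                           pos + np.array([0.0, 0.0, 1.0]), "C", False)
            )
            serial += 1
            atoms.append(
                AtomRecord(serial, "CG", "ASP", "A", resnum, " ", pos, "C", False)
            )
        if spec.na_structures is not None and s in spec.na_structures:
            if spec.na_site is None:
                raise ValueError("na_structures given without na_site")
            serial += 1
            resnum += 1
            atoms.append(
                AtomRecord(
                    serial, "NA", "NA", "A", resnum, " ",
                    np.asarray(spec.na_site, float)
                    + rng.normal(scale=spec.jitter_sd, size=3),
                    "NA", True,
                )
            )
        models.append(StructureModel(structure_id, gene, atoms))
        manifest_rows.append({"structure_id": structure_id, "gene_label": gene})

    manifest = pd.DataFrame(manifest_rows)
    truth = {
        "consensus_sites": spec.consensus_sites,
        "n_consensus": len(spec.consensus_sites),
        "decoys": decoy_log,
        "na_site": spec.na_site,
    }
    return models, manifest, truth


def simulate_titration(spec: TitrationSpec) -> pd.DataFrame:
    """4PL responses with Gaussian noise on a pH grid.

    Returns a tidy table (replicate, ph, response); the generating
    parameters are attached under ``.attrs['truth']``.
    """
    rng = np.random.default_rng(spec.seed)
    sd = spec.noise_sd_frac * (spec.top - spec.bottom)
    rows = []
    for rep in range(spec.replicates):
        clean = spec.bottom + (spec.top - spec.bottom) / (
            1.0 + np.power(10.0, spec.hill_slope * (spec.ph_grid - spec.ph50))
        )
        noisy = clean + rng.normal(scale=sd, size=len(spec.ph_grid)) if sd > 0 else clean
        for ph, resp in zip(spec.ph_grid, noisy):
            rows.append({"replicate": rep, "ph": float(ph), "response": float(resp)})
    table = pd.DataFrame(rows)
    table.attrs["truth"] = {
        "bottom": spec.bottom,
        "top": spec.top,
        "ph50": spec.ph50,
        "hill_slope": spec.hill_slope,
    }
    return table


def simulate_dvp(
    effects: dict[str, float],
    noise_sd: float = 0.05,
    seed: int = 0,
    wt_fluorescence: float = 1000.0,
    threshold: float = 0.5,
) -> pd.DataFrame:
    """Variant fluorescence table with lognormal noise around known effects.

    ``effects`` maps mutant name to its true fold change vs WT (WT itself
    must be present with effect 1.0; an effect of 0 marks a dead variant).
    The returned table carries the measured fluorescence and the ground-truth
    call at the given log2-fold-change threshold.
    """
    if "WT" not in effects:
        raise ValueError("effects must include 'WT'")
    rng = np.random.default_rng(seed)
    rows = []
    for mutant in effects:
        effect = effects[mutant]
        if effect < 0:
            raise ValueError(f"negative fold change for {mutant}")
        true_f = wt_fluorescence * effect
        measured = (
            0.0 if true_f == 0 else float(true_f * rng.lognormal(mean=0.0, sigma=noise_sd))
        )
        if effect == 0:
            call = "nonfunctional"
        else:
            fc = math.log2(effect)
            call = "increase" if fc > threshold else "decrease" if fc < -threshold else "no_change"
        rows.append(
            {
                "mutant": mutant,
                "fluorescence": measured,
                "true_effect": effect,
                "true_call": call,
            }
        )
    return pd.DataFrame(rows)
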