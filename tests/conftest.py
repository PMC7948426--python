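"""Shared fixtures: small geometric solids and synthetic structures."""

import numpy as np
import pytest

from protonsense.phinder_core import build_surface
from protonsense.structure_io import AtomRecord, StructureModel


def ca_model(points, structure_id="fix", gene_label="FIX", resname="GLY"):
    """A model with one Cα per residue at the given positions."""
    atoms = [
        AtomRecord(i + 1, "CA", resname, "A", i + 1, " ", np.asarray(p, float), "C", False)
        for i, p in enumerate(points)
    ]
    return StructureModel(structure_id, gene_label, atoms)


def fibonacci_sphere(n, radius):
    i = np.arange(n) + 0.5
    phi = np.arccos(1 - 2 * i / n)
    theta = np.pi * (1 + 5**0.5) * i
    return radius * np.stack(
        [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)], axis=1
    )


@pytest.fixture(scope="session")
def cube_model():
    pts = [(x, y, z) for x in (0.0, 5.0) for y in (0.0, 5.0) for z in (0.0, 5.0)]
    return ca_model(pts, "cube", "CUBE")


@pytest.fixture(scope="session")
def cube_mesh(cube_model):
    return build_surface(cube_model)


@pytest.fixture(scope="session")
def ball_model():
    """100 Cα on a 15 Å sphere plus seeded interior filler.

    The interior points make the solid a filled ball: a hollow shell of
    exactly cospherical points is a degenerate input for the Delaunay-based
    surface (every tetrahedron shares the same circumsphere).
    """
    rng = np.random.default_rng(7)
    surface = fibonacci_sphere(100, 15.0)
    inner = rng.uniform(-1, 1, size=(260, 3))
    inner = inner[np.linalg.norm(inner, axis=1) <= 1.0] * 13.0
    return ca_model(np.vstack([surface, inner]), "ball", "BALL")


@pytest.fixture(scope="session")
def ball_mesh(ball_model):
    return build_surface(ball_model)
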