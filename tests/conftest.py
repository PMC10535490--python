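import numpy as np
import pytest

from icmsas import AtomicModel, ScatteringCurve


@pytest.fixture
def flat_curve():
    q = np.linspace(0.005, 0.5, 100)
    return ScatteringCurve(q, np.full(100, 2.0), np.full(100, 0.1))


def make_point_model(coords, b=1.0, axis=None):
    coords = np.asarray(coords, dtype=float).reshape(-1, 3)
    n = len(coords)
    return AtomicModel(np.array(["X"] * n, dtype=object), coords,
                       np.zeros(n), b_explicit=np.full(n, b), axis=axis)


def make_rod(length, radius, n, seed=0, axis_z=True):
    """Uniform random point scatterers filling a cylinder."""
    rng = np.random.default_rng(seed)
    z = rng.uniform(-length / 2, length / 2, n)
    phi = rng.uniform(0, 2 * np.pi, n)
    r = radius * np.sqrt(rng.random(n))
    pts = np.column_stack([r * np.cos(phi), r * np.sin(phi), z])
    return make_point_model(pts, axis=np.array([0.0, 0.0, 1.0]))


def make_ball(radius, n, seed=0):
    """Uniform random point scatterers filling a sphere."""
    rng = np.random.default_rng(seed)
    v = rng.standard_normal((n, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    v *= radius * rng.random(n)[:, None] ** (1 / 3)
    return make_point_model(v)


GLY_PDB = """\
ATOM      1  N   GLY A   1      11.104   6.134  -6.504  1.00  0.00           N
ATOM      2  CA  GLY A   1      11.639   6.071  -5.147  1.00  0.00           C
ATOM      3  C   GLY A   1      10.729   6.768  -4.123  1.00  0.00           C
END
"""

SER_PDB = """\
ATOM      1  N   SER A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  SER A   1       1.458   0.000   0.000  1.00  0.00           C
ATOM      3  C   SER A   1       2.009   1.420   0.000  1.00  0.00           C
ATOM      4  O   SER A   1       1.251   2.390   0.000  1.00  0.00           O
ATOM      5  CB  SER A   1       1.986  -0.773  -1.207  1.00  0.00           C
ATOM      6  OG  SER A   1       3.392  -0.829  -1.148  1.00  0.00           O
END
"""

TWO_MODEL_PDB = """\
MODEL        1
ATOM      1  N   GLY A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  GLY A   1       1.458   0.000   0.000  1.00  0.00           C
ATOM      3  C   GLY A   1       2.009   1.420   0.000  1.00  0.00           C
ATOM      4  O   GLY A   1       1.251   2.390   0.000  1.00  0.00           O
ATOM      5  OXT GLY A   1       3.200   1.500   0.000  1.00  0.00           O
ENDMDL
MODEL        2
ATOM      6  N   GLY A   1       5.000   0.000   0.000  1.00  0.00           N
ATOM      7  CA  GLY A   1       6.458   0.000   0.000  1.00  0.00           C
ATOM      8  C   GLY A   1       7.009   1.420   0.000  1.00  0.00           C
ATOM      9  O   GLY A   1       6.251   2.390   0.000  1.00  0.00           O
ATOM     10  OXT GLY A   1       8.200   1.500   0.000  1.00  0.00           O
ENDMDL
END
"""
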