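import numpy as np
import pytest

from cryodeform.gaussian_model import GaussianModel
from cryodeform.io_formats import CTFParams


@pytest.fixture(scope="session")
def hinge_study():
    """Default hinge scene with both half-set VAEs trained.

    Session-scoped: the end-to-end tests (parameter recovery, inverse
    round trip, reconstruction benefit, half-set agreement) share one
    training run.
    """
    from cryodeform import deformation_vae as dv
    from cryodeform.gaussian_model import initialize_from_map, render_density
    from cryodeform.halfset_validation import split_for_validation
    from cryodeform.synthetic_data import make_hinge_scene, simulate_particles

    scene = make_hinge_scene(seed=1)
    stack, truth = simulate_particles(scene)
    vol = render_density(scene.model, (scene.box, scene.pixel_size))
    model0 = initialize_from_map(vol, 0.05 * vol.data.max(),
                                 scene.n_gaussians, seed=2)
    _, val_idx = split_for_validation(len(stack), 0.10, seed=0)
    cfg = dv.TrainingConfig.for_small_problem(seed=0)
    t1, t2 = dv.train_two_halfsets(stack, model0, cfg, val_idx=val_idx)
    return dict(scene=scene, stack=stack, truth=truth, vol=vol,
                t1=t1, t2=t2, val_idx=val_idx)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_model(rng):
    """Eight Gaussians well inside a 32-box at 2 A/pixel."""
    centers = rng.uniform(-18.0, 18.0, size=(8, 3))
    return GaussianModel(centers, [4.0], [1.5], np.ones((1, 8)))


@pytest.fixture
def typical_ctf():
    return CTFParams(defocus_u=12000.0, defocus_v=14000.0, astig_angle=30.0)


ALA_PDB = """\
ATOM      1  N   ALA A   1      11.104   6.134  -6.504  1.00  0.00           N
ATOM      2  CA  ALA A   1      11.639   6.071  -5.147  1.00  0.00           C
ATOM      3  C   ALA A   1      12.685   7.182  -5.033  1.00  0.00           C
ATOM      4  O   ALA A   1      13.339   7.378  -6.107  1.00  0.00           O
ATOM      5  CB  ALA A   1      12.217   4.699  -4.809  1.00  0.00           C
END
"""

ALA_PDB_WITH_H = ALA_PDB.replace("END\n", """\
ATOM      6  H   ALA A   1      10.000   6.000  -7.000  1.00  0.00           H
ATOM      7  HA  ALA A   1      11.000   6.200  -4.500  1.00  0.00           H
END
""")

TRP_PDB = """\
ATOM      1  N   TRP A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  TRP A   1       1.458   0.000   0.000  1.00  0.00           C
ATOM      3  C   TRP A   1       2.009   1.420   0.000  1.00  0.00           C
ATOM      4  O   TRP A   1       1.251   2.390   0.000  1.00  0.00           O
ATOM      5  CB  TRP A   1       2.000  -0.760  -1.220  1.00  0.00           C
ATOM      6  CG  TRP A   1       3.480  -0.900  -1.280  1.00  0.00           C
ATOM      7  CD1 TRP A   1       4.200  -1.980  -0.870  1.00  0.00           C
ATOM      8  CD2 TRP A   1       4.420   0.050  -1.800  1.00  0.00           C
ATOM      9  NE1 TRP A   1       5.550  -1.760  -1.070  1.00  0.00           N
ATOM     10  CE2 TRP A   1       5.720  -0.520  -1.670  1.00  0.00           C
ATOM     11  CE3 TRP A   1       4.250   1.320  -2.370  1.00  0.00           C
ATOM     12  CZ2 TRP A   1       6.850   0.150  -2.090  1.00  0.00           C
ATOM     13  CZ3 TRP A   1       5.370   1.990  -2.790  1.00  0.00           C
ATOM     14  CH2 TRP A   1       6.650   1.410  -2.650  1.00  0.00           C
END
"""

GLY_GLY_PDB = """\
ATOM      1  N   GLY A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  GLY A   1       1.458   0.000   0.000  1.00  0.00           C
ATOM      3  C   GLY A   1       2.009   1.420   0.000  1.00  0.00           C
ATOM      4  O   GLY A   1       1.251   2.390   0.000  1.00  0.00           O
ATOM      5  N   GLY A   2       3.320   1.540   0.000  1.00  0.00           N
ATOM      6  CA  GLY A   2       3.980   2.840   0.000  1.00  0.00           C
ATOM      7  C   GLY A   2       5.480   2.700   0.000  1.00  0.00           C
ATOM      8  O   GLY A   2       6.020   1.600   0.000  1.00  0.00           O
END
"""

# one adenosine nucleotide (coordinates approximate but geometrically sane)
ADE_PDB = """\
ATOM      1  P     A A   1       0.000   0.000   0.000  1.00  0.00           P
ATOM      2  OP1   A A   1      -1.200   0.800   0.300  1.00  0.00           O
ATOM      3  OP2   A A   1       0.200  -1.300   0.600  1.00  0.00           O
ATOM      4  O5'   A A   1       1.200   0.900   0.300  1.00  0.00           O
ATOM      5  C5'   A A   1       2.500   0.400   0.600  1.00  0.00           C
ATOM      6  C4'   A A   1       3.500   1.500   0.700  1.00  0.00           C
ATOM      7  O4'   A A   1       3.700   2.000  -0.650  1.00  0.00           O
ATOM      8  C3'   A A   1       4.900   1.100   1.150  1.00  0.00           C
ATOM      9  O3'   A A   1       5.100   1.700   2.430  1.00  0.00           O
ATOM     10  C2'   A A   1       5.800   1.700   0.070  1.00  0.00           C
ATOM     11  O2'   A A   1       6.100   3.060   0.330  1.00  0.00           O
ATOM     12  C1'   A A   1       4.950   1.600  -1.190  1.00  0.00           C
ATOM     13  N9    A A   1       5.350   0.500  -2.070  1.00  0.00           N
ATOM     14  C8    A A   1       4.700  -0.680  -2.290  1.00  0.00           C
ATOM     15  N7    A A   1       5.300  -1.480  -3.130  1.00  0.00           N
ATOM     16  C5    A A   1       6.450  -0.790  -3.480  1.00  0.00           C
ATOM     17  C6    A A   1       7.490  -1.090  -4.360  1.00  0.00           C
ATOM     18  N6    A A   1       7.540  -2.230  -5.060  1.00  0.00           N
ATOM     19  N1    A A   1       8.480  -0.180  -4.500  1.00  0.00           N
ATOM     20  C2    A A   1       8.430   0.960  -3.800  1.00  0.00           C
ATOM     21  N3    A A   1       7.500   1.360  -2.950  1.00  0.00           N
ATOM     22  C4    A A   1       6.530   0.430  -2.840  1.00  0.00           C
END
"""


@pytest.fixture
def ala_pdb(tmp_path):
    p = tmp_path / "ala.pdb"
    p.write_text(ALA_PDB)
    return p


@pytest.fixture
def ala_pdb_with_h(tmp_path):
    p = tmp_path / "ala_h.pdb"
    p.write_text(ALA_PDB_WITH_H)
    return p


@pytest.fixture
def trp_pdb(tmp_path):
    p = tmp_path / "trp.pdb"
    p.write_text(TRP_PDB)
    return p


@pytest.fixture
def ade_pdb(tmp_path):
    p = tmp_path / "ade.pdb"
    p.write_text(ADE_PDB)
    return p


@pytest.fixture
def glygly_pdb(tmp_path):
    p = tmp_path / "glygly.pdb"
    p.write_text(GLY_GLY_PDB)
    return p
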