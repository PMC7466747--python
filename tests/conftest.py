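import numpy as np
import pytest

from ntckit.synthetic import (
    DEFAULT_GEOMETRY,
    SyntheticSpec,
    build_dinucleotide,
    build_polymer,
    generate_reference,
)

B_LIKE_TORSIONS = {
    "delta1": 84.0, "epsilon1": -170.0, "zeta1": -95.0,
    "alpha2": -62.0, "beta2": 175.0, "gamma2": 55.0, "delta2": 140.0,
    "chi1": -98.0, "chi2": -140.0, "mu": -20.0,
}


@pytest.fixture(scope="session")
def reference3():
    """3-class synthetic reference set with labeled training vectors."""
    return generate_reference(SyntheticSpec(n_classes=3, samples_per_class=30, seed=7))


@pytest.fixture(scope="session")
def refset3(reference3):
    return reference3[0]


@pytest.fixture(scope="session")
def b_like_step():
    return build_dinucleotide(B_LIKE_TORSIONS)


@pytest.fixture(scope="session")
def homopolymer(refset3):
    """6-residue chain built from five copies of the first synthetic class."""
    code = refset3.codes[0]
    return build_polymer([code] * 5, refset3)


def random_rotation(rng):
    """Proper rotation matrix from a random quaternion (no scipy)."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])


def transform_step(step, R, t):
    """Rigidly transformed copy of a DinucleotideStep."""
    from dataclasses import replace

    from ntckit.structure_io import DinucleotideStep

    atoms = {role: replace(atom, xyz=R @ atom.xyz + t)
             for role, atom in step.atoms.items()}
    out = DinucleotideStep(first=step.first, second=step.second, atoms=atoms)
    out.step_name = step.step_name
    return out
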