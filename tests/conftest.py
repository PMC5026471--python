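"""Shared fixtures: small, fast toy models used across the suite."""

import numpy as np
import pytest

from pumpsel import (
    CosineTerm,
    IonParameters,
    RestraintSpec,
    TorsionProfileModel,
    build_binding_site,
    build_bulk_droplet,
    default_ion_parameters,
)


@pytest.fixture(scope="session")
def na_params() -> IonParameters:
    return default_ion_parameters("Na")


@pytest.fixture(scope="session")
def k_params() -> IonParameters:
    return default_ion_parameters("K")


@pytest.fixture(scope="session")
def close_k_params(na_params) -> IonParameters:
    """A K-like ion only slightly larger than Na: good endpoint overlap."""
    return IonParameters(species="K", epsilon=na_params.epsilon * 1.2,
                         rmin_half=na_params.rmin_half + 0.06)


@pytest.fixture
def small_site():
    """Four-ligand site with one acidic ligand; cheap to sample."""
    return build_binding_site({
        "n_ligands": 4, "charged": ["L1"], "scenario_id": "small_site",
    })


@pytest.fixture
def restrained_site(small_site):
    from dataclasses import replace
    from pumpsel.toy_system import restraint_geometry
    r, th, ps = restraint_geometry([1e-9, 0.0, 0.0], small_site.anchors_p)
    return replace(small_site,
                   restraint=RestraintSpec(r0=r, theta0=th, psi0=ps))


@pytest.fixture
def droplet():
    return build_bulk_droplet({"n_solvent": 6})


@pytest.fixture
def triple_well():
    """Asymmetric three-well torsion profile (rotamer-like)."""
    return TorsionProfileModel(torsion=(CosineTerm(1.2, 3, 0.0),
                                        CosineTerm(0.5, 1, 40.0)))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20230915)
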