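"""Synthetic radical-pair systems for testing and scaled-down studies.

Real cryptochrome radical pairs (FAD with tryptophan or tyrosine) carry up
to 21 magnetic nuclei whose hyperfine tensors come from quantum-chemical
calculations.  This module generates pairs with the same statistical
structure — anisotropic tensors of realistic magnitude for spin-1 nitrogens
and spin-1/2 protons — so every analysis stage runs without external data:

* random ensembles (``random_radical``) with configurable isotropic scale
  and anisotropy fraction;
* ``fixture_systems``: the small named systems used throughout the tests —
  a one-proton pair, a two-proton anisotropic pair (the dense-oracle
  workhorse), a reference-probe pair (all couplings on one radical), the
  aligned identical axial-tensor family, and a flavin-like radical carrying
  axial stand-ins for the dominant N5/N10 nitrogen couplings.

The flavin N5/N10 tensors shipped here are synthetic stand-ins of
literature magnitude (axial, ~50 and ~17 MHz longitudinal components), not
quantum-chemical values; real tensors can be supplied through the config
format without code changes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .spin_core import (
    EulerOrientation,
    NucleusSpec,
    RadicalPairSpec,
    RadicalSpec,
)

__all__ = ["GeneratorConfig", "random_radical", "random_pair", "fixture_systems"]

TOPOLOGIES = ("symmetric", "reference_probe", "axial_aligned")


@dataclass(frozen=True)
class GeneratorConfig:
    """Ensemble parameters for random radical generation.

    ``scale`` is the isotropic coupling magnitude in MHz (protons in
    flavin/tryptophan radicals have couplings of order 0.1-1 mT, i.e. a few
    to ~30 MHz; the default 10 MHz sits in that range).  ``anisotropy``
    in [0, 1] scales a random symmetric traceless part added to a*I.
    """

    n_protons: int = 1
    n_nitrogens: int = 0
    scale: float = 10.0
    anisotropy: float = 0.5
    topology: str = "symmetric"
    seed: int = 0

    def __post_init__(self):
        if self.n_protons < 0 or self.n_nitrogens < 0:
            raise ValueError("nucleus counts must be >= 0")
        if self.scale <= 0:
            raise ValueError("scale must be positive")
        if not 0.0 <= self.anisotropy <= 1.0:
            raise ValueError("anisotropy fraction must lie in [0, 1]")
        if self.topology not in TOPOLOGIES:
            raise ValueError(f"unknown topology {self.topology!r}")


def _random_tensor(rng: np.random.Generator, scale: float, anis: float) -> np.ndarray:
    """a*I + anis*scale*W with W symmetric, traceless, unit-normalized."""
    a = scale * (1.0 + 0.3 * rng.standard_normal())
    w = rng.standard_normal((3, 3))
    w = (w + w.T) / 2.0
    w -= np.trace(w) / 3.0 * np.eye(3)
    norm = np.linalg.norm(w)
    if norm > 0:
        w /= norm
    return a * np.eye(3) + anis * scale * w


def random_radical(config: GeneratorConfig, name: str = "random") -> RadicalSpec:
    """A radical with randomly drawn hyperfine tensors (deterministic per seed)."""
    rng = np.random.default_rng(config.seed)
    nuclei = []
    for i in range(config.n_nitrogens):
        nuclei.append(
            NucleusSpec(
                f"N{i + 1}", 1.0,
                _random_tensor(rng, config.scale, config.anisotropy),
            )
        )
    for i in range(config.n_protons):
        nuclei.append(
            NucleusSpec(
                f"H{i + 1}", 0.5,
                _random_tensor(rng, config.scale, config.anisotropy),
            )
        )
    return RadicalSpec(name=name, nuclei=tuple(nuclei))


def random_pair(
    config_a: GeneratorConfig,
    config_b: GeneratorConfig,
    b0: float = 50.0,
    k: float = 1.0,
) -> RadicalPairSpec:
    return RadicalPairSpec(
        radical_a=random_radical(config_a, "A"),
        radical_b=random_radical(config_b, "B"),
        b0=b0, k=k,
    )


def _axial(transverse: float, longitudinal: float) -> np.ndarray:
    return np.diag([transverse, transverse, longitudinal])


def flavinlike_radical() -> RadicalSpec:
    """Flavin-like radical: two spin-1 nitrogens with axial tensors.

    Synthetic stand-ins of literature magnitude for the dominant N5/N10
    couplings of the flavin radical anion (axial tensors with ~49.2 and
    ~16.9 MHz longitudinal and small negative transverse components).
    """
    return RadicalSpec(
        name="flavin_like",
        nuclei=(
            NucleusSpec("N5", 1.0, _axial(-2.6, 49.2)),
            NucleusSpec("N10", 1.0, _axial(-0.4, 16.9)),
        ),
    )


def fixture_systems(
    transverse: float = 1.0, seed: int = 2024
) -> dict[str, RadicalPairSpec]:
    """Named small radical-pair systems used across tests and analyses.

    Keys
    ----
    one_proton
        One spin-1/2 nucleus, isotropic 10 MHz, on radical A; 8-dim.
    two_proton_aniso
        One anisotropic proton on each radical; 16-dim (dense-oracle size).
    three_nucleus
        Flavin-like radical A (2 x N) with one random proton on B; 72-dim.
    reference_probe_5
        Five random couplings on radical A, bare radical B.
    axial_aligned_3 / axial_aligned_3_t0
        Three identical aligned axial tensors (10 MHz longitudinal) on
        radical A with transverse component ``transverse`` / exactly zero —
        the regime contrasting sustained vs decaying electron coherence.
    flavinlike_random
        Flavin-like radical A with three random protons on radical B; the
        5-nucleus workhorse for scaled-down orientation scans.
    """
    rng_tensor = np.random.default_rng(seed)

    one_proton = RadicalPairSpec(
        radical_a=RadicalSpec(
            "A", (NucleusSpec("H1", 0.5, 10.0 * np.eye(3)),)
        ),
        radical_b=RadicalSpec("B"),
    )

    ta = _random_tensor(rng_tensor, 10.0, 0.8)
    tb = _random_tensor(rng_tensor, 8.0, 0.8)
    two_proton_aniso = RadicalPairSpec(
        radical_a=RadicalSpec("A", (NucleusSpec("H1", 0.5, ta),)),
        radical_b=RadicalSpec("B", (NucleusSpec("H1", 0.5, tb),)),
    )

    three_nucleus = RadicalPairSpec(
        radical_a=flavinlike_radical(),
        radical_b=RadicalSpec(
            "B", (NucleusSpec("H1", 0.5, _random_tensor(rng_tensor, 10.0, 0.6)),)
        ),
    )

    probe = random_radical(
        GeneratorConfig(n_protons=4, n_nitrogens=1, scale=12.0,
                        anisotropy=0.6, seed=seed + 1),
        name="probe",
    )
    reference_probe_5 = RadicalPairSpec(
        radical_a=probe, radical_b=RadicalSpec("bare")
    )

    def axial_pair(t: float) -> RadicalPairSpec:
        nuclei = tuple(
            NucleusSpec(f"H{i + 1}", 0.5, _axial(t, 10.0)) for i in range(3)
        )
        return RadicalPairSpec(
            radical_a=RadicalSpec("axial", nuclei),
            radical_b=RadicalSpec("bare"),
        )

    flavinlike_random = RadicalPairSpec(
        radical_a=flavinlike_radical(),
        radical_b=random_radical(
            GeneratorConfig(n_protons=3, scale=10.0, anisotropy=0.6,
                            seed=seed + 2),
            name="partner",
        ),
    )

    return {
        "one_proton": one_proton,
        "two_proton_aniso": two_proton_aniso,
        "three_nucleus": three_nucleus,
        "reference_probe_5": reference_probe_5,
        "axial_aligned_3": axial_pair(transverse),
        "axial_aligned_3_t0": axial_pair(0.0),
        "flavinlike_random": flavinlike_random,
    }
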