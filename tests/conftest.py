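import numpy as np
import pytest

from matenet import simstand


@pytest.fixture(scope="session")
def small_stand():
    """A 50-adult mixed stand with strong differentiation."""
    return simstand.generate_stand(30, 20, n_loci=12, alleles_per_locus=10,
                                   differentiation=0.8, extent=(100.0, 100.0), seed=11)


@pytest.fixture(scope="session")
def small_progeny(small_stand):
    return simstand.simulate_mating(
        small_stand, n_mothers=15, offspring_per_mother=20,
        dispersal_scale=40.0, compatibility=0.2, immigration=0.2, seed=12,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)


def sib_dyads(kind: str, m: int, n_loci: int, n_alleles: int, seed: int):
    """Simulate dyads of known kinship from uniform allele frequencies."""
    rng = np.random.default_rng(seed)

    def adults(k):
        return rng.integers(0, n_alleles, size=(k, n_loci, 2)).astype(np.int16)

    def child(mo, fa):
        pm = rng.integers(0, 2, size=(len(mo), n_loci))
        pf = rng.integers(0, 2, size=(len(mo), n_loci))
        mat = np.take_along_axis(mo, pm[..., None], axis=2)[..., 0]
        pat = np.take_along_axis(fa, pf[..., None], axis=2)[..., 0]
        return np.stack([mat, pat], axis=2).astype(np.int16)

    fa = adults(m)
    mo1, mo2 = adults(m), adults(m)
    if kind == "full":
        return child(mo1, fa), child(mo1, fa)
    if kind == "half":
        return child(mo1, fa), child(mo2, fa)
    if kind == "unrelated":
        return child(mo1, fa), child(mo2, adults(m))
    raise ValueError(kind)
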