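import numpy as np
import pandas as pd
import pytest

from phylokaryo import (
    AncestrySpec,
    GenotypeMatrix,
    SamplePanel,
    inject_missingness,
    simulate_ancestral_model,
    simulate_queries,
    simulate_reference_panel,
)
from phylokaryo.simulate import combine_panels


def make_gm(dosage, chroms=None, positions=None, samples=None, classes=None,
            anchors=None):
    """Hand-build a GenotypeMatrix from a dosage array (rows = samples)."""
    dosage = np.asarray(dosage, dtype=np.int8)
    n_s, n_l = dosage.shape
    samples = samples or [f"s{i}" for i in range(n_s)]
    chroms = chroms or ["1"] * n_l
    positions = positions or list(range(100, 100 + 10 * n_l, 10))
    classes = classes or ["SNP"] * n_l
    anchors = anchors if anchors is not None else [c == "INDEL" for c in classes]
    loci = pd.DataFrame(
        {
            "chrom": chroms,
            "pos": positions,
            "ref": ["A"] * n_l,
            "alt": ["G"] * n_l,
            "variant_class": classes,
            "indel_anchor": anchors,
        }
    )
    return GenotypeMatrix(samples, loci, dosage)


@pytest.fixture(scope="session")
def small_model():
    """2 chromosomes x 800 loci; mixture of fixed and shared loci."""
    return simulate_ancestral_model(
        n_chrom=2, loci_per_chrom=800, prop_fixed=0.3, seed=11
    )


@pytest.fixture(scope="session")
def small_refs(small_model):
    gm, panel, truth = simulate_reference_panel(small_model, seed=12)
    return gm, panel, truth


@pytest.fixture(scope="session")
def small_dataset(small_model, small_refs):
    """References + F1 + pure queries with 12.6% missingness injected."""
    gm_refs, panel, _ = small_refs
    specs = [
        AncestrySpec.f1("q_f1", small_model.chrom_lengths),
        AncestrySpec.pure("q_ret", "RET", small_model.chrom_lengths),
        AncestrySpec.pure("q_max", "MAX", small_model.chrom_lengths),
    ]
    gm_q, truth = simulate_queries(small_model, specs, seed=13)
    gm = combine_panels(gm_refs, gm_q)
    gm, _ = inject_missingness(gm, 0.126, seed=14)
    roles = dict(panel.roles)
    roles.update({s.sample: "QUERY" for s in specs})
    return gm, SamplePanel(roles), truth
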