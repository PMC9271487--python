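import numpy as np
import pytest

import ovismap as ov


def random_panel(rng: np.random.Generator, n: int, m: int, missing_rate: float = 0.05) -> ov.GenotypePanel:
    """Unstructured random panel (no LD model) for codec/oracle tests."""
    d = rng.integers(0, 3, size=(n, m)).astype(np.int8)
    if missing_rate:
        d = np.where(rng.random(d.shape) < missing_rate, np.int8(ov.MISSING), d)
    pairs = [("A", "G"), ("C", "T"), ("T", "G"), ("G", "C")]
    variants = [
        ov.VariantMeta(f"rs{j}", "1", 1000 + 50 * j, *pairs[j % 4]) for j in range(m)
    ]
    return ov.GenotypePanel(
        samples=[f"s{i}" for i in range(n)], variants=variants, dosages=d
    )


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory):
    """The canonical generated fixture suite (seed 7)."""
    out = tmp_path_factory.mktemp("fixtures")
    manifest = ov.make_fixture_suite(out, seed=7)
    return out, manifest


@pytest.fixture(scope="session")
def fixture_panel(fixture_dir):
    out, _ = fixture_dir
    return ov.read_plink(out / "panel")


@pytest.fixture(scope="session")
def fixture_ref(fixture_panel):
    ref, log = ov.build_reference_table(fixture_panel)
    return ref


@pytest.fixture(scope="session")
def fixture_studies(fixture_dir, fixture_ref):
    out, _ = fixture_dir
    studies = {}
    for name, key in (("gwas_a.tsv", "trait_a"), ("gwas_b.tsv", "trait_b")):
        raw, _ = ov.parse_sumstats(out / name, column_map=ov.GWAS_COLUMN_MAP)
        studies[key] = ov.harmonize(ov.complete_statistics(raw), fixture_ref, study_key=key)
    return studies
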