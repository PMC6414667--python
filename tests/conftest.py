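import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

BASES = np.array(list("ACGT"))


def random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(BASES, size=length))


def revcomp(s: str) -> str:
    return s.translate(str.maketrans("ACGT", "TGCA"))[::-1]


def mutate(seq: str, n_sub: int, rng: np.random.Generator, n_indel: int = 0) -> str:
    out = list(seq)
    if n_sub:
        for p in rng.choice(len(out), size=n_sub, replace=False):
            out[p] = rng.choice([b for b in "ACGT" if b != out[p]])
    for _ in range(n_indel):
        p = int(rng.integers(1, len(out) - 1))
        if rng.random() < 0.5:
            out.insert(p, str(rng.choice(BASES)))
        else:
            del out[p]
    return "".join(out)


@pytest.fixture(scope="session")
def reference_20kb():
    rng = np.random.default_rng(421)
    return {"contigA": random_seq(rng, 20000)}


@pytest.fixture(scope="session")
def reference_index(reference_20kb):
    from phagetrace.recruitment import ReferenceIndex

    return ReferenceIndex(reference_20kb, k=15)


@pytest.fixture(scope="session")
def psba_profile():
    """Calibrated PSSM over a 4-group synthetic psbA reference set."""
    from phagetrace.markers import build_profile, calibrate_threshold
    from phagetrace.synthetic import MarkerSetConfig, generate_marker_references

    refs = generate_marker_references(
        MarkerSetConfig(
            groups=(
                "cyano_synechococcus",
                "cyano_prochlorococcus",
                "T4like",
                "T7like",
            ),
            seed=17,
        )
    )
    profile = build_profile(refs)
    calibrate_threshold(profile, read_length=200, n_null=4000, target_fpr=1e-3, seed=17)
    return refs, profile


@pytest.fixture(scope="session")
def psba_genes(psba_profile):
    from phagetrace.synthetic import back_translate

    refs, _ = psba_profile
    genes = {}
    for i, rid in enumerate(refs.ids):
        genes.setdefault(refs.labels[rid], []).append(back_translate(refs.sequences[i], seed=i))
    return genes
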