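import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from utrkit.io import LibraryManifest, UtrRecord
from utrkit.prep import strip_augs

BASES = list("ACGT")


def random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(BASES, size=length))


def random_member(rng: np.random.Generator, length: int = 100) -> str:
    """A random standardized (AUG-free) library sequence."""
    return strip_augs(random_dna(rng, length), rng)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_manifest() -> LibraryManifest:
    rng = np.random.default_rng(77)
    records = [
        UtrRecord(id=f"u{i:03d}", sequence=random_member(rng))
        for i in range(20)
    ]
    return LibraryManifest(records=records)


@pytest.fixture(scope="session")
def screen_library() -> LibraryManifest:
    """1000-member library used by the end-to-end screen checks."""
    rng = np.random.default_rng(7)
    records = [
        UtrRecord(id=f"u{i:04d}", sequence=random_member(rng))
        for i in range(1000)
    ]
    return LibraryManifest(records=records)


@pytest.fixture(scope="session")
def surrogate_dataset():
    """Featurized simulated Ribo/RNA cohort shared by the surrogate checks.

    n=2000 transcripts at 2M read depth, planted k-mer TE signal at 2:1
    signal-to-noise; the regression target is the count-recovered TE.
    """
    from utrkit.features import UtrFeaturizer
    from utrkit.simulate import simulate_ribo_rna, simulate_transcriptome
    from utrkit.te import quantify

    tx = simulate_transcriptome(2000, seed=1)
    rna, rpf, truth = simulate_ribo_rna(tx, depth=2_000_000, seed=2)
    quant = quantify(rna, rpf, tx.set_index("transcript_id")["length_nt"])
    keep = (quant["pass_filter"] & quant["te"].notna()).to_numpy()
    feat = UtrFeaturizer().fit()
    X = feat.transform(list(zip(tx["utr_seq"], tx["cds_seq"].str[:15])))
    y = quant["te"].to_numpy()
    return {
        "X": X[keep],
        "y": y[keep],
        "feature_names": feat.feature_names_,
        "truth": truth,
        "quant": quant,
        "keep": keep,
    }


@pytest.fixture(scope="session")
def planted_screen(screen_library):
    """Planted 2-fold screen (50/1000 members) plus its analysis."""
    from utrkit.screen import ScreenEnrichmentModel
    from utrkit.simulate import planted_screen_strengths, simulate_screen

    strengths, planted = planted_screen_strengths(
        screen_library.ids, n_enhanced=50, fold=2.0, seed=3
    )
    counts, metadata, truth = simulate_screen(
        screen_library, strengths, depth=200_000, seed=12
    )
    model = ScreenEnrichmentModel().fit(counts, metadata)
    return {
        "counts": counts,
        "metadata": metadata,
        "planted": planted,
        "model": model,
        "truth": truth,
    }
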