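import numpy as np
import pytest

from ms2deep import (FixturePlan, Spectrum, motif_table, neutral_loss_table,
                     simulate_feature_table)


@pytest.fixture(scope="session")
def motifs():
    return motif_table()


@pytest.fixture(scope="session")
def losses():
    return neutral_loss_table()


@pytest.fixture(scope="session")
def planted_tables():
    """Positive/negative feature tables with recorded ground truth."""
    return simulate_feature_table(FixturePlan(seed=7, n_features=40))


def random_spectrum(rng: np.random.Generator, n_peaks: int = 6,
                    ion_mode: str = "positive", sid: str = "s") -> Spectrum:
    mz = np.sort(rng.uniform(60, 800, size=n_peaks))
    # keep peaks > 0.05 Th apart so greedy matching is unambiguous
    mz = mz + np.arange(n_peaks) * 0.1
    inten = rng.uniform(1e3, 1e6, size=n_peaks)
    return Spectrum(id=sid, ion_mode=ion_mode, peaks=tuple(zip(mz, inten)),
                    precursor_mz=float(mz[-1] + rng.uniform(1, 30)))
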