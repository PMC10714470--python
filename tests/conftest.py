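import numpy as np
import pytest

from glycofp import (
    AugmentationConfig,
    LibrarySpec,
    build_corpus,
    make_library,
    render,
)


@pytest.fixture(scope="session")
def small_library():
    """Default-structure library (4 known + 7 OOD) at seed 11."""
    return make_library(LibrarySpec(seed=11))


@pytest.fixture(scope="session")
def small_corpus(small_library):
    """A scaled-down surrogate corpus: 4 classes x 120 augmentations."""
    rng = np.random.default_rng(5)
    known = [t for t in small_library if not t.name.startswith("OOD:")]
    by_class = {t.name: [render(t, rng=rng) for _ in range(4)] for t in known}
    return build_corpus(by_class, AugmentationConfig(n_per_class=120, seed=6))
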