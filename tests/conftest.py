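import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def small_library():
    """A small deterministic fixture library: 2 classes, 6 series each."""
    from potencyclm.fixtures import FixtureSpec, generate_library

    spec = FixtureSpec(
        n_classes=2, n_series_per_class=6, series_size_range=(4, 6), seed=42
    )
    return generate_library(spec)


@pytest.fixture(scope="session")
def library_pairs(small_library):
    """Curated analogue pairs per class from the small library."""
    from potencyclm.analogues import build_series
    from potencyclm.pairing import curate_triples, enumerate_pairs

    by_class = {}
    for class_id, compounds in small_library.classes.items():
        series = build_series(compounds, max_sites=3)
        by_class[class_id] = enumerate_pairs(series)
    pooled = curate_triples([p for ps in by_class.values() for p in ps])
    out = {}
    for p in pooled:
        out.setdefault(p.cpd_a.class_id, []).append(p)
    return out
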