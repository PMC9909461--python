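import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_cohort():
    """The study-shaped synthetic cohort (32 individuals, 30 loci, 3 trios)."""
    from tandemscape.synthetic import default_cohort_spec, generate_cohort

    return generate_cohort(default_cohort_spec(), seed=1)


@pytest.fixture(scope="session")
def annotated_cohort(default_cohort):
    """Per-haplotype annotations + harmonized catalog for the default cohort."""
    from tandemscape.harmonize import assign_ids
    from tandemscape.repeats import annotate_gene

    sequences = default_cohort.sequences()
    rng = np.random.default_rng(1234)
    per_hap = {
        lab: annotate_gene(seq, seed=int(rng.integers(2**31)), contig=lab)
        for lab, seq in sorted(sequences.items())
    }
    catalog = assign_ids(per_hap, sequences)
    return default_cohort, per_hap, catalog


@pytest.fixture(scope="session")
def catalog_truth_map(annotated_cohort):
    """Map catalog TR ids to generator locus names via shared intervals."""
    cohort, _, catalog = annotated_cohort
    mapping = {}
    for locus in catalog:
        lab, ann = sorted(locus.annotations.items())[0]
        for name, truth in cohort.loci.items():
            if lab in truth.intervals and abs(
                truth.intervals[lab][0] - ann.interval.start
            ) <= 10:
                mapping[locus.tr_id] = name
    return mapping


@pytest.fixture(scope="session")
def small_cohort():
    """A reduced cohort (6 individuals, 11 loci) for cheaper integration tests."""
    from tandemscape.synthetic import default_cohort_spec, generate_cohort

    return generate_cohort(
        default_cohort_spec(n_individuals=6, n_invariant=6), seed=5
    )
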