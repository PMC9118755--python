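import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

from magcnse.ensemble import EnsembleConfig
from magcnse.evaluation import CvPlan, cross_validate, summarize_cv
from magcnse.pipeline import compute_views
from magcnse.representation import GcnConfig
from magcnse.synthetic_data import SyntheticConfig, generate_dataset

BENCH_SEEDS = (0, 1, 2)


@pytest.fixture(scope="session")
def tiny_dataset():
    """A small planted-block dataset for fast structural tests."""
    cfg = SyntheticConfig(
        n_lncrna=30, n_disease=16, n_blocks=2, p_in=0.5, p_out=0.02,
        seq_len=60, mutation_rate=0.1, seed=7,
    )
    ld, seqs, dag, blocks = generate_dataset(cfg)
    return cfg, ld, seqs, dag, blocks


@pytest.fixture(scope="session")
def tiny_views(tiny_dataset):
    _, ld, seqs, dag, _ = tiny_dataset
    views_l, views_d = compute_views(ld, seqs, dag)
    return views_l, views_d


@pytest.fixture(scope="session")
def bench_dataset():
    """The 100 x 50, 4-block benchmark family used by the recovery tests."""
    cfg = SyntheticConfig(seed=11)
    ld, seqs, dag, blocks = generate_dataset(cfg)
    views_l, views_d = compute_views(ld, seqs, dag)
    return cfg, ld, seqs, dag, blocks, views_l, views_d


def run_bench_cv(bench, seed, *, ablation=None, shuffle_labels=False):
    """One 5-fold CV of the pipeline on the benchmark, transductive protocol."""
    _, ld, _, _, _, views_l, views_d = bench
    flags = {
        None: {},
        "fgl": {"first_layer_only": True},
        "natt": {"use_attention": False},
        "nattcnn": {"use_attention": False, "use_cnn": False},
        "ncnn": {"use_cnn": False},
    }[ablation]
    gcn = GcnConfig(seed=seed, leakage_safe=False, **flags)
    table = cross_validate(
        ld,
        views_d[0],
        views_l[1],
        CvPlan(k=5, repeats=1, seed=seed),
        gcn,
        EnsembleConfig.compact(seed=seed),
        shuffle_labels=shuffle_labels,
    )
    return summarize_cv(table)


@pytest.fixture(scope="session")
def bench_full_cv(bench_dataset):
    """Full-model CV summaries for the three benchmark seeds."""
    return {seed: run_bench_cv(bench_dataset, seed) for seed in BENCH_SEEDS}
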