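import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from straintrack import reference, synth

settings.register_profile(
    "ci", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

# composition used for the parameter-recovery study: 8 strains spanning
# dominant to rare (2%) members
RECOVERY_COMPOSITION = [0.30, 0.25, 0.15, 0.10, 0.08, 0.06, 0.04, 0.02]


@pytest.fixture(scope="session")
def small_universe():
    """4 x 20 kb genomes with 20% shared content and their k=31 index."""
    genomes = synth.simulate_genomes(4, 20_000, shared_fraction=0.2,
                                     n_shared_blocks=2, seed=101)
    index = reference.build_unique_index(genomes, k=31)
    return genomes, index


@pytest.fixture(scope="session")
def recovery_universe():
    """The 8-strain, 100 kb, 20%-shared universe used for parameter recovery."""
    genomes = synth.simulate_genomes(8, 100_000, shared_fraction=0.2,
                                     n_shared_blocks=4, seed=11)
    index = reference.build_unique_index(genomes, k=31)
    composition = {g.strain_id: v for g, v in zip(genomes, RECOVERY_COMPOSITION)}
    return genomes, index, composition


@pytest.fixture(scope="session")
def recovery_estimates(recovery_universe):
    """Informative-mode abundance estimates from 100,000 reads, error-free and
    at 0.5% substitution error, against the planted composition."""
    from straintrack import quant

    genomes, index, composition = recovery_universe
    out = {}
    for tag, error_rate in (("error_free", 0.0), ("noisy", 0.005)):
        reads, _ = synth.simulate_reads(genomes, composition, 100_000, 150,
                                        error_rate, seed=12)
        counts, unassigned = quant.classify_reads(reads, index)
        rel = quant.scale_abundance(counts, index)
        out[tag] = {
            "estimates": rel,
            "counts": counts,
            "unassigned": unassigned,
            "max_abs_error": max(abs(rel[s] - composition[s]) for s in composition),
        }
    return out


def permutation_p_two_sample(x, y, n_reps=20_000, seed=0):
    """Permutation p-value for |mean(x) - mean(y)| by label reshuffling."""
    rng = np.random.default_rng(seed)
    pooled = np.concatenate([x, y])
    n1 = len(x)
    obs = abs(np.mean(x) - np.mean(y))
    order = np.argsort(rng.random((n_reps, len(pooled))), axis=1)
    perm = pooled[order]
    diff = np.abs(perm[:, :n1].mean(axis=1) - perm[:, n1:].mean(axis=1))
    return (1 + np.sum(diff >= obs - 1e-12)) / (n_reps + 1)


def permutation_p_paired(pre, post, n_reps=20_000, seed=0):
    """Permutation p for the mean paired difference by random sign flips."""
    rng = np.random.default_rng(seed)
    d = np.asarray(post) - np.asarray(pre)
    obs = abs(d.mean())
    signs = rng.choice([-1.0, 1.0], size=(n_reps, len(d)))
    sim = np.abs((signs * d).mean(axis=1))
    return (1 + np.sum(sim >= obs - 1e-12)) / (n_reps + 1)


def permutation_p_anova(groups, n_reps=20_000, seed=0):
    """Permutation p for the between-group sum of squares by label reshuffling."""
    rng = np.random.default_rng(seed)
    sizes = [len(g) for g in groups]
    pooled = np.concatenate(groups)
    grand = pooled.mean()

    def ssb(vals):
        out = 0.0
        start = 0
        for n in sizes:
            out += n * (vals[start:start + n].mean() - grand) ** 2
            start += n
        return out

    obs = ssb(pooled)
    count = 0
    for _ in range(n_reps):
        count += ssb(rng.permutation(pooled)) >= obs - 1e-12
    return (1 + count) / (n_reps + 1)
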