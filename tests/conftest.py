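import numpy as np
import pytest

from dectico.features import FeatureMatrix


def make_planted_matrix(seed, n_samples=40, n_features=1000, n_informative=10, effect=2.0):
    """Balanced two-class matrix: informative columns differ in mean by
    `effect` between classes, the rest are standard-normal noise."""
    rng = np.random.default_rng(seed)
    half = n_samples // 2
    y = np.array([1] * half + [-1] * (n_samples - half))
    X = rng.normal(size=(n_samples, n_features))
    X[:, :n_informative] += (effect / 2.0) * y[:, None]
    names = [
        f"inf{j}" if j < n_informative else f"noise{j}" for j in range(n_features)
    ]
    return FeatureMatrix(
        sample_ids=[f"s{i}" for i in range(n_samples)],
        feature_names=names,
        values=X,
        labels=y,
    )


@pytest.fixture
def planted_matrix():
    return make_planted_matrix(seed=7)


@pytest.fixture
def small_labeled_matrix():
    """10 samples, 2 well-separated 1-D clusters."""
    y = np.array([1] * 5 + [-1] * 5)
    x = np.concatenate([np.linspace(10.0, 10.4, 5), np.linspace(0.0, 0.4, 5)])
    return FeatureMatrix(
        sample_ids=[f"s{i}" for i in range(10)],
        feature_names=["x"],
        values=x[:, None],
        labels=y,
    )


@pytest.fixture
def fasta_manifest(tmp_path):
    """Four tiny FASTA samples with two labels, written to disk."""
    rng = np.random.default_rng(42)
    bases = np.array(list("ACGT"))
    rows = []
    for i in range(4):
        sid = f"s{i}"
        path = tmp_path / f"{sid}.fasta"
        with open(path, "w") as fh:
            for r in range(30):
                seq = "".join(rng.choice(bases, size=50))
                fh.write(f">{sid}_r{r}\n{seq}\n")
        label = "disease" if i < 2 else "control"
        rows.append(f"{sid}\t{sid}.fasta\t{label}")
    manifest_path = tmp_path / "manifest.tsv"
    manifest_path.write_text("sample_id\tpaths\tlabel\n" + "\n".join(rows) + "\n")
    return manifest_path
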