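import numpy as np
import pandas as pd

from ontoprot.embedding import EmbeddingMatrix


def write_tables(tmp_path, concepts, relationships):
    """Write concept/relationship row lists as the TSVs the loader reads."""
    cpath, rpath = tmp_path / "concepts.tsv", tmp_path / "relationships.tsv"
    cdf = pd.DataFrame(concepts, columns=["id", "active", "term"])
    rdf = pd.DataFrame(relationships, columns=["sourceId", "destinationId", "typeId"])
    cdf.to_csv(cpath, sep="\t", index=False)
    rdf.to_csv(rpath, sep="\t", index=False)
    return cpath, rpath


def blob_embedding(k, n_per=20, std=3.0, seed=0, dim=128):
    """Planted spherical Gaussian clusters wrapped as an embedding."""
    from sklearn.datasets import make_blobs

    X, y = make_blobs(
        n_samples=k * n_per, centers=k, n_features=dim, cluster_std=std,
        center_box=(-10.0, 10.0), random_state=seed,
    )
    ids = [f"n{i:04d}" for i in range(len(X))]
    return EmbeddingMatrix(ids, X.astype(np.float32), dim, 10, seed), ids, y
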