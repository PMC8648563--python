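import numpy as np
import pandas as pd
import pytest
from anndata import AnnData
from hypothesis import HealthCheck, settings

import nichecomm as nc

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def wnt_db() -> nc.InteractionDatabase:
    """Small curated-style database with one heteromeric WNT receptor."""
    return nc.InteractionDatabase(
        genes=["WNT7A", "FZD5", "LRP6", "JAG1", "NOTCH2", "DKK1"],
        complexes={"WNT_receptor": ["FZD5", "LRP6"]},
        interactions=pd.DataFrame(
            [
                ("I1", "WNT7A", "WNT_receptor", "pathway=WNT"),
                ("I2", "JAG1", "NOTCH2", "pathway=NOTCH"),
            ],
            columns=["interaction_id", "partner_a", "partner_b", "annotation"],
        ),
        version="test",
    )


@pytest.fixture
def db_csv_dir(tmp_path):
    """The same database serialized in the CSV dialect the loader reads."""
    gene_path = tmp_path / "genes.csv"
    complex_path = tmp_path / "complexes.csv"
    interaction_path = tmp_path / "interactions.csv"
    gene_path.write_text("gene_id\nWNT7A\nFZD5\nLRP6\nJAG1\nNOTCH2\nDKK1\n")
    complex_path.write_text("complex_id,subunit_1,subunit_2,subunit_3\nWNT_receptor,FZD5,LRP6,\n")
    interaction_path.write_text(
        "interaction_id,partner_a,partner_b,annotation\n"
        "I1,WNT7A,WNT_receptor,pathway=WNT\n"
        "I2,JAG1,NOTCH2,pathway=NOTCH\n"
    )
    return {"genes": gene_path, "complexes": complex_path, "interactions": interaction_path}


def make_adata(counts: np.ndarray, clusters, genes=None, donors=None) -> AnnData:
    counts = np.asarray(counts)
    n, g = counts.shape
    obs = pd.DataFrame(
        {
            "cluster": list(map(str, clusters)),
            "donor": list(donors) if donors is not None else ["d1"] * n,
        },
        index=[f"cell{i}" for i in range(n)],
    )
    var = pd.DataFrame(index=list(genes) if genes is not None else [f"g{j}" for j in range(g)])
    adata = AnnData(X=counts, obs=obs, var=var)
    adata.obs["total_counts"] = counts.sum(axis=1)
    return adata


@pytest.fixture
def toy_summary() -> nc.ClusterExpressionSummary:
    """Tabulated toy summary over the WNT/NOTCH gene panel, two clusters."""
    genes = ["WNT7A", "FZD5", "LRP6", "JAG1", "NOTCH2", "DKK1"]
    mean = pd.DataFrame(
        [[4.0, 5.0, 1.0, 3.0, 2.0, 0.0], [0.5, 2.0, 2.0, 0.0, 4.0, 0.0]],
        index=["A", "B"],
        columns=genes,
    )
    frac = pd.DataFrame(
        [[0.9, 0.5, 0.05, 0.10, 0.099, 0.0], [0.2, 0.4, 0.6, 0.0, 0.8, 0.0]],
        index=["A", "B"],
        columns=genes,
    )
    return nc.ClusterExpressionSummary(
        mean_expr=mean, frac_expr=frac, n_cells=pd.Series({"A": 10, "B": 10})
    )
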