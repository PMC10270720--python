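"""Plain-text artifact readers and writers.

Formats: one node x time TSV per subject (nodes as rows, no header),
parcellation.tsv (node_id, network_id, network_name), subjects.tsv
(subject_id, confounds, test_01..test_14 with empty string for missing),
adjacency TSVs with a JSON sidecar, truth.json for planted parameters.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .graph import AdjacencyMatrix
from .synth import ParcellationSpec, SyntheticCohort, subject_table

__all__ = [
    "write_cohort",
    "read_timeseries",
    "read_parcellation",
    "read_subjects",
    "write_adjacency",
    "read_adjacency",
]


def write_cohort(cohort: SyntheticCohort, outdir: str | Path) -> Path:
    outdir = Path(outdir)
    (outdir / "timeseries").mkdir(parents=True, exist_ok=True)
    n = len(cohort.timeseries)
    ids = [f"sub-{i + 1:04d}" for i in range(n)]
    for sid, ts in zip(ids, cohort.timeseries):
        np.savetxt(outdir / "timeseries" / f"{sid}.tsv", ts, delimiter="\t")
    parc = cohort.parcellation
    names = parc.network_names or tuple(
        f"network_{k}" for k in range(1, parc.network_count + 1)
    )
    pd.DataFrame(
        {
            "node_id": np.arange(1, parc.node_count + 1),
            "network_id": parc.labels,
            "network_name": [names[l - 1] for l in parc.labels],
        }
    ).to_csv(outdir / "parcellation.tsv", sep="\t", index=False)
    subject_table(cohort).to_csv(outdir / "subjects.tsv", sep="\t", index=False)
    truth = {
        "seed": cohort.spec.seed,
        "effect_beta": cohort.spec.effect_beta,
        "confound_betas": list(cohort.spec.confound_betas),
        "segregation_sd": cohort.spec.segregation_sd,
        "latent_cognition": cohort.truth["latent_cognition"].tolist(),
        "segregation": cohort.truth["segregation"].tolist(),
    }
    (outdir / "truth.json").write_text(json.dumps(truth, indent=1))
    return outdir


def read_timeseries(path: str | Path) -> np.ndarray:
    return np.loadtxt(path, delimiter="\t", ndmin=2)


def read_parcellation(path: str | Path) -> ParcellationSpec:
    table = pd.read_csv(path, sep="\t")
    labels = table["network_id"].to_numpy(dtype=int)
    names = None
    if "network_name" in table:
        uniq = table.drop_duplicates("network_id").sort_values("network_id")
        names = tuple(uniq["network_name"])
    return ParcellationSpec(len(table), int(labels.max()), labels, names)


def read_subjects(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t").set_index("subject_id")


def write_adjacency(adj: AdjacencyMatrix, path: str | Path) -> None:
    path = Path(path)
    np.savetxt(path, adj.w, delimiter="\t")
    sidecar = {"alpha": adj.alpha, "sign_policy": adj.sign_policy}
    path.with_suffix(".json").write_text(json.dumps(sidecar))


def read_adjacency(path: str | Path) -> AdjacencyMatrix:
    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    return AdjacencyMatrix(
        w=np.loadtxt(path, delimiter="\t", ndmin=2),
        sign_policy=meta["sign_policy"],
        alpha=meta["alpha"],
    )
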