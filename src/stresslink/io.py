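"""Readers and writers for the pipeline's interchange formats.

All tables are tab-delimited text with a header row; gene sets use the
GMT dialect (name, description, tab-separated members); simulation truth
is JSON.  Floats are serialized at 6 significant digits and p-values are
kept in scientific notation so they never round to 0.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .diffexpr import CountMatrix
from .simulate import CohortTruth

SURVIVAL_COLUMNS = ["strain", "assay", "replicate", "animal_id",
                    "time", "event", "control_group"]


def write_table(df: pd.DataFrame, path, index: bool = True) -> None:
    df.to_csv(path, sep="\t", index=index, float_format="%.6g")


def write_survival(table: pd.DataFrame, path) -> None:
    write_table(table[SURVIVAL_COLUMNS], path, index=False)


def read_survival(path) -> pd.DataFrame:
    """Validated individual-level survival table."""
    tab = pd.read_csv(path, sep="\t")
    missing = set(SURVIVAL_COLUMNS) - set(tab.columns)
    if missing:
        raise ValueError(f"survival table missing columns: {sorted(missing)}")
    bad_t = tab.index[~(pd.to_numeric(tab["time"], errors="coerce") > 0)]
    if len(bad_t):
        raise ValueError(f"non-positive or non-numeric time in rows "
                         f"{list(bad_t[:5])}")
    if not tab["event"].isin([0, 1]).all():
        bad = tab.index[~tab["event"].isin([0, 1])]
        raise ValueError(f"event must be 0/1; bad rows {list(bad[:5])}")
    return tab


def write_counts(counts: pd.DataFrame, metadata: pd.DataFrame,
                 counts_path, metadata_path) -> None:
    write_table(counts, counts_path)
    write_table(metadata, metadata_path)


def read_counts(counts_path, metadata_path) -> CountMatrix:
    """Count matrix + metadata, cross-validated into a CountMatrix."""
    counts = pd.read_csv(counts_path, sep="\t", index_col=0)
    meta = pd.read_csv(metadata_path, sep="\t", index_col=0)
    if not np.issubdtype(counts.to_numpy().dtype, np.number):
        raise ValueError("counts table contains non-numeric entries")
    return CountMatrix(counts=counts, metadata=meta)


def read_gmt(path) -> dict[str, set[str]]:
    """GMT gene sets: name, description, then tab-separated members.

    Duplicate set names are an error; duplicate members are deduplicated
    (sets), empty member lists are allowed.
    """
    sets: dict[str, set[str]] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 2:
            raise ValueError(f"{path}:{lineno}: GMT line needs at least "
                             f"name and description")
        name = fields[0]
        if name in sets:
            raise ValueError(f"{path}:{lineno}: duplicate set name {name!r}")
        sets[name] = {m for m in fields[2:] if m}
    return sets


def write_gmt(sets: dict[str, set[str]], path,
              description: str = "stresslink") -> None:
    lines = []
    for name, members in sets.items():
        lines.append("\t".join([name, description] + sorted(members)))
    Path(path).write_text("\n".join(lines) + "\n")


def write_truth(truth: CohortTruth, path) -> None:
    payload = {
        "gene_module": truth.gene_module,
        "coupling_lifespan": truth.coupling_lifespan,
        "coupling_stress": truth.coupling_stress,
        "strain_traits": truth.strain_traits.to_dict(orient="index"),
        "expected_mean_survival":
            truth.expected_mean_survival.to_dict(orient="index"),
    }
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def read_truth(path) -> CohortTruth:
    d = json.loads(Path(path).read_text())
    return CohortTruth(
        gene_module=d["gene_module"],
        coupling_lifespan=d["coupling_lifespan"],
        coupling_stress=d["coupling_stress"],
        strain_traits=pd.DataFrame.from_dict(d["strain_traits"],
                                             orient="index"),
        expected_mean_survival=pd.DataFrame.from_dict(
            d["expected_mean_survival"], orient="index"),
    )
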