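"""Tab-separated readers and writers for every pipeline artefact.

All identifiers are opaque strings.  Pairwise evidence (Y2H and literature)
shares one format, disambiguated through a sources table; complexes,
homology, disorder annotations, posteriors, networks, modules and
enrichment results each have their own flat TSV.
"""

from __future__ import annotations

import json
import os
from typing import Dict, List, Optional, Tuple

import pandas as pd

from .scan import ModulePartition
from .simulate import SimulatedData
from .types import (HUMAN, ComplexRecord, EvidenceSet, PosteriorScores,
                    ProteinUniverse)

__all__ = ["write_simulated", "read_evidence", "read_disorder",
           "write_posteriors", "read_posteriors", "write_params_trace",
           "write_modules", "read_modules", "write_manifest"]


class FormatError(ValueError):
    """Raised for malformed input files, naming the file and line."""


def _load_tsv(path: str, columns: Dict[str, type]) -> pd.DataFrame:
    if not os.path.exists(path):
        raise FormatError(f"{path}: file not found")
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except pd.errors.ParserError as exc:
        raise FormatError(f"{path}: {exc}") from exc
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise FormatError(f"{path}, line 1: missing columns {missing}")
    for name, typ in columns.items():
        if typ is str:
            continue
        converted = pd.to_numeric(df[name], errors="coerce")
        bad = converted.isna() & df[name].ne("")
        if bad.any() or converted.isna().any():
            line = int(bad.idxmax() if bad.any()
                       else converted.isna().idxmax()) + 2
            raise FormatError(f"{path}, line {line}: cannot parse "
                              f"column {name!r} as {typ.__name__}")
        df[name] = converted.astype(typ)
    return df


def _write(df: pd.DataFrame, path: str) -> None:
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# evidence bundles
# ---------------------------------------------------------------------------

def write_simulated(sim: SimulatedData, outdir: str) -> None:
    """Write a simulated data set as the evidence TSV bundle plus truth."""
    os.makedirs(outdir, exist_ok=True)
    uni = sim.universe
    _write(pd.DataFrame({"protein_id": uni.proteins,
                         "organism": [uni.organism[p] for p in uni.proteins]}),
           os.path.join(outdir, "proteins.tsv"))

    ev = sim.evidence
    pairwise = ev.y2h.rename(columns={"a": "protein_a", "b": "protein_b"})
    sources = sorted(set(pairwise["source_id"])) if len(pairwise) else []
    source_rows = [(s, "y2h", uni.organism[
        pairwise[pairwise["source_id"] == s]["protein_a"].iloc[0]])
        for s in sources]
    lit = ev.literature
    if len(lit):
        lit_part = pd.DataFrame({
            "protein_a": lit["a"], "protein_b": lit["b"],
            "source_id": "lit_" + lit["channel"], "replicate": 1,
            "observed": lit["observed"]})
        pairwise = pd.concat([pairwise, lit_part], ignore_index=True)
        for chan in sorted(set(lit["channel"])):
            source_rows.append((f"lit_{chan}",
                                f"literature_{chan.lower()}", HUMAN))
    _write(pairwise, os.path.join(outdir, "pairwise.tsv"))
    _write(pd.DataFrame(source_rows,
                        columns=["source_id", "kind", "organism"]),
           os.path.join(outdir, "sources.tsv"))

    _write(pd.DataFrame(
        [(c.bait, ",".join(sorted(c.members)), c.experiment_id)
         for c in ev.complexes],
        columns=["bait", "members", "experiment_id"]),
        os.path.join(outdir, "complexes.tsv"))

    _write(ev.homology.rename(columns={"human": "human_protein"}),
           os.path.join(outdir, "homology.tsv"))
    _write(sim.disorder, os.path.join(outdir, "disorder.tsv"))

    truth_edges = [(a, b) for (a, b), v in sorted(sim.truth.z.items()) if v]
    _write(pd.DataFrame(truth_edges, columns=["protein_a", "protein_b"]),
           os.path.join(outdir, "ground_truth_edges.tsv"))
    _write(pd.DataFrame(sorted(sim.truth.x.items()),
                        columns=["protein_id", "x"]),
           os.path.join(outdir, "ground_truth_selfact.tsv"))
    _write(pd.DataFrame(sorted(sim.config.theta_true.to_dict().items()),
                        columns=["component", "value"]),
           os.path.join(outdir, "ground_truth_params.tsv"))


def read_evidence(indir: str) -> EvidenceSet:
    """Reassemble an :class:`EvidenceSet` from an evidence TSV bundle."""
    prot = _load_tsv(os.path.join(indir, "proteins.tsv"),
                     {"protein_id": str, "organism": str})
    universe = ProteinUniverse(prot["protein_id"], prot["organism"])

    pw_path = os.path.join(indir, "pairwise.tsv")
    pairwise = _load_tsv(pw_path, {"protein_a": str, "protein_b": str,
                                   "source_id": str, "replicate": int,
                                   "observed": int})
    sources = _load_tsv(os.path.join(indir, "sources.tsv"),
                        {"source_id": str, "kind": str, "organism": str})
    kind = dict(zip(sources["source_id"], sources["kind"]))
    unknown = [s for s in pairwise["source_id"].unique() if s not in kind]
    if unknown:
        raise FormatError(f"{pw_path}: source ids missing from sources.tsv: "
                          f"{unknown[:3]}")
    kinds = pairwise["source_id"].map(kind)
    y2h = pairwise[kinds == "y2h"].rename(
        columns={"protein_a": "a", "protein_b": "b"})
    lit_rows = []
    for chan in ("h", "l"):
        sub = pairwise[kinds == f"literature_{chan}"]
        if len(sub):
            lit_rows.append(pd.DataFrame({
                "a": sub["protein_a"], "b": sub["protein_b"],
                "channel": chan.upper(), "observed": sub["observed"]}))
    literature = pd.concat(lit_rows, ignore_index=True) if lit_rows else None

    cx = _load_tsv(os.path.join(indir, "complexes.tsv"),
                   {"bait": str, "members": str, "experiment_id": str})
    complexes = [ComplexRecord(
        bait=row.bait,
        members=frozenset(m for m in row.members.split(",") if m),
        experiment_id=row.experiment_id)
        for row in cx.itertuples(index=False)]

    hom = _load_tsv(os.path.join(indir, "homology.tsv"),
                    {"human_protein": str, "ortholog": str,
                     "organism": str, "identity": float})
    hom = hom.rename(columns={"human_protein": "human"})
    return EvidenceSet.build(universe, y2h=y2h if len(y2h) else None,
                             literature=literature, complexes=complexes,
                             homology=hom if len(hom) else None)


def read_disorder(path: str) -> pd.DataFrame:
    return _load_tsv(path, {"protein_id": str,
                            "longest_disorder_length": int})


def read_truth_edges(indir: str) -> List[Tuple[str, str]]:
    df = _load_tsv(os.path.join(indir, "ground_truth_edges.tsv"),
                   {"protein_a": str, "protein_b": str})
    return [(row.protein_a, row.protein_b)
            for row in df.itertuples(index=False)]


# ---------------------------------------------------------------------------
# fit artefacts
# ---------------------------------------------------------------------------

def write_posteriors(scores: PosteriorScores, path: str) -> None:
    _write(scores.to_frame(), path)


def read_posteriors(path: str) -> PosteriorScores:
    df = _load_tsv(path, {"protein_a": str, "protein_b": str,
                          "posterior": float})
    return PosteriorScores({(row.protein_a, row.protein_b): row.posterior
                            for row in df.itertuples(index=False)})


def write_params_trace(trace: List[Dict[str, float]], path: str) -> None:
    rows = []
    for it, theta in enumerate(trace):
        for comp, val in theta.items():
            rows.append((it, comp, val))
    _write(pd.DataFrame(rows, columns=["iteration", "component", "estimate"]),
           path)


# ---------------------------------------------------------------------------
# clustering artefacts
# ---------------------------------------------------------------------------

def write_modules(partition: ModulePartition, path: str) -> None:
    rows = [(p, str(lab)) for p, lab in sorted(partition.labels.items())]
    rows += [(p, "HUB") for p in sorted(partition.hubs)]
    rows += [(p, "OUTLIER") for p in sorted(partition.outliers)]
    _write(pd.DataFrame(rows, columns=["protein", "module"]), path)


def read_modules(path: str, epsilon: float = float("nan"),
                 mu: int = 2) -> ModulePartition:
    df = _load_tsv(path, {"protein": str, "module": str})
    labels, hubs, outliers = {}, set(), set()
    for row in df.itertuples(index=False):
        if row.module == "HUB":
            hubs.add(row.protein)
        elif row.module == "OUTLIER":
            outliers.add(row.protein)
        else:
            try:
                labels[row.protein] = int(row.module)
            except ValueError as exc:
                raise FormatError(f"{path}: bad module label "
                                  f"{row.module!r}") from exc
    return ModulePartition(labels=labels, hubs=hubs, outliers=outliers,
                           epsilon=epsilon, mu=mu)


def write_manifest(payload: dict, path: str) -> None:
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
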