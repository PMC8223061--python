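"""Input/output and harmonization of expression matrices, labels, annotations
and qPCR Ct tables.

Conventions
-----------
* Expression matrices are genes-in-rows, samples-in-columns (the GEO
  series-matrix orientation). Transposed input is never guessed; callers who
  hold a transposed table must transpose it themselves.
* All tabular files are plain tab- or comma-delimited text with a header row
  of sample IDs and gene/probe IDs in the first column. Lines starting with
  ``!`` (GEO series-matrix metadata) are skipped.
* Missing expression values are rejected at parse time unless per-gene median
  imputation is explicitly requested; they are never silently propagated.

The four medulloblastoma subgroups are referred to throughout by their
consensus names ``WNT``, ``SHH``, ``Group3`` and ``Group4``; the historical
aliases (Group 1/2, Group C/D, A–D) are normalized on input via a fixed
alias table.
"""

from __future__ import annotations

import io
import json
import math
import warnings
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CLASS_ORDER",
    "CLASS_ALIASES",
    "ExpressionMatrix",
    "SubgroupLabels",
    "GeneAnnotation",
    "CtTable",
    "ParseError",
    "read_expression_matrix",
    "write_expression_matrix",
    "read_labels",
    "write_labels",
    "read_annotation",
    "read_ct_table",
    "collapse_probes",
    "align_to_gene_set",
    "write_manifest",
]

#: Canonical subgroup order used everywhere a deterministic class order is
#: needed (pair sorting, confusion-matrix axes, vote tie-breaking).
CLASS_ORDER: tuple[str, ...] = ("WNT", "SHH", "Group3", "Group4")

# Alias keys are matched after lowercasing and stripping spaces/underscores/
# hyphens, so "Group 3", "group_3" and "GROUP-3" all normalize identically.
CLASS_ALIASES: dict[str, str] = {
    "wnt": "WNT", "group1": "WNT", "groupa": "WNT", "a": "WNT", "grp1": "WNT",
    "shh": "SHH", "group2": "SHH", "groupb": "SHH", "b": "SHH", "grp2": "SHH",
    "group3": "Group3", "groupc": "Group3", "c": "Group3", "grp3": "Group3",
    "g3": "Group3", "grpc": "Group3",
    "group4": "Group4", "groupd": "Group4", "d": "Group4", "grp4": "Group4",
    "g4": "Group4", "grpd": "Group4",
}

#: Default upper bound for plausible qPCR cycle-threshold values.
MAX_CYCLES_DEFAULT: float = 40.0

_SEPS = {"tsv": "\t", "csv": ","}


class ParseError(ValueError):
    """Raised when an input file violates a format invariant."""


def normalize_class(name: str) -> str:
    """Map a subgroup label (any documented alias) to its canonical name."""
    key = name.strip().lower().replace(" ", "").replace("_", "").replace("-", "")
    try:
        return CLASS_ALIASES[key]
    except KeyError:
        raise ParseError(
            f"unknown subgroup label {name!r}; expected one of "
            f"{CLASS_ORDER} or a documented alias"
        ) from None


@dataclass
class ExpressionMatrix:
    """A genes x samples matrix of log-scale normalized expression values.

    ``data`` is a float DataFrame whose index holds gene (or probe) IDs and
    whose columns hold sample IDs; both must be unique and all cells finite.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        idx, cols = self.data.index, self.data.columns
        if idx.duplicated().any():
            dup = idx[idx.duplicated()][0]
            raise ParseError(f"duplicate gene identifier {dup!r}")
        if cols.duplicated().any():
            dup = cols[cols.duplicated()][0]
            raise ParseError(f"duplicate sample identifier {dup!r}")
        values = self.data.to_numpy()
        if values.size and not np.isfinite(values).all():
            g, s = np.argwhere(~np.isfinite(values))[0]
            raise ParseError(
                f"non-finite expression value at gene {idx[g]!r}, sample {cols[s]!r}"
            )
        self.data = self.data.astype(float)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def n_genes(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


@dataclass
class SubgroupLabels:
    """Per-sample subgroup assignment over the four consensus classes."""

    assignments: dict[str, str]

    def __post_init__(self) -> None:
        for sample, cls in self.assignments.items():
            if cls not in CLASS_ORDER:
                raise ParseError(
                    f"label for sample {sample!r} is {cls!r}, not a canonical class"
                )

    @property
    def classes(self) -> tuple[str, ...]:
        """Classes present, in canonical order."""
        present = set(self.assignments.values())
        return tuple(c for c in CLASS_ORDER if c in present)

    def samples_of(self, cls: str) -> list[str]:
        return [s for s, c in self.assignments.items() if c == cls]

    def subset(self, samples: Iterable[str]) -> "SubgroupLabels":
        samples = list(samples)
        missing = [s for s in samples if s not in self.assignments]
        if missing:
            raise KeyError(f"samples without labels: {missing[:5]}")
        return SubgroupLabels({s: self.assignments[s] for s in samples})

    def __len__(self) -> int:
        return len(self.assignments)


@dataclass
class GeneAnnotation:
    """Probe-to-gene-symbol mapping (many-to-one and one-to-many allowed)."""

    mapping: dict[str, str]


@dataclass
class CtTable:
    """qPCR cycle-threshold table with a designated reference gene.

    Invariants: the reference-gene row exists, is complete, and every
    non-missing Ct lies in ``[0, max_cycles]``. Missing values (NaN) are
    tolerated here only so an explicit policy can resolve them downstream.
    """

    data: pd.DataFrame
    reference_gene: str
    max_cycles: float = MAX_CYCLES_DEFAULT

    def __post_init__(self) -> None:
        if self.reference_gene not in self.data.index:
            raise ParseError(
                f"reference gene {self.reference_gene!r} not present in Ct table"
            )
        ref = self.data.loc[self.reference_gene]
        if ref.isna().any():
            bad = ref.index[ref.isna()][0]
            raise ParseError(
                f"reference gene {self.reference_gene!r} has a missing Ct for "
                f"sample {bad!r}"
            )
        vals = self.data.to_numpy()
        with np.errstate(invalid="ignore"):
            out_of_range = (vals < 0) | (vals > self.max_cycles)
        if np.nansum(out_of_range):
            g, s = np.argwhere(np.nan_to_num(out_of_range)).tolist()[0]
            raise ParseError(
                f"Ct value out of [0, {self.max_cycles}] at gene "
                f"{self.data.index[g]!r}, sample {self.data.columns[s]!r}"
            )

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def _read_table(path: str | Path, dialect: str) -> pd.DataFrame:
    if dialect not in _SEPS:
        raise ValueError(f"dialect must be one of {sorted(_SEPS)}, got {dialect!r}")
    path = Path(path)
    text = path.read_text()
    kept = "\n".join(line for line in text.splitlines() if not line.startswith("!"))
    df = pd.read_csv(io.StringIO(kept), sep=_SEPS[dialect], index_col=0, dtype=str,
                     float_precision="round_trip")
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return df


def _coerce_numeric(df: pd.DataFrame, path: str | Path, impute_missing: bool) -> pd.DataFrame:
    numeric = df.apply(pd.to_numeric, errors="coerce")
    # distinguish "was text" from "was empty/NA"
    bad = numeric.isna() & df.notna() & (df.apply(lambda c: c.str.strip().str.lower()).isin(
        ["na", "nan", "", "null", "undetermined"]) == False)  # noqa: E712
    if bad.to_numpy().any():
        g, s = np.argwhere(bad.to_numpy())[0]
        raise ParseError(
            f"{path}: non-numeric cell at gene {df.index[g]!r}, sample "
            f"{df.columns[s]!r}: {df.iat[g, s]!r}"
        )
    # to_numeric above is detection only: its fast parser can be 1 ulp off,
    # so the kept values go through numpy's correctly rounded strtod instead
    missing = numeric.isna()
    if missing.to_numpy().any() and not impute_missing:
        g, s = np.argwhere(missing.to_numpy())[0]
        raise ParseError(
            f"{path}: missing value at gene {numeric.index[g]!r}, sample "
            f"{numeric.columns[s]!r} (imputation disabled)"
        )
    exact = df.where(~missing, "nan").astype(float)
    if missing.to_numpy().any():
        medians = exact.median(axis=1)
        exact = exact.apply(lambda row: row.fillna(medians[row.name]), axis=1)
    return exact


def read_expression_matrix(
    path: str | Path,
    dialect: str = "tsv",
    *,
    impute_missing: bool = False,
) -> ExpressionMatrix:
    """Read a genes x samples expression matrix from delimited text.

    The first row holds sample IDs, the first column gene (or probe) IDs.
    ``!``-prefixed lines are skipped so GEO series-matrix value blocks parse
    directly. Duplicate identifiers and non-numeric cells raise
    :class:`ParseError` naming the offender; missing values raise unless
    ``impute_missing`` requests per-gene median imputation.
    """
    df = _read_table(path, dialect)
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise ParseError(f"{path}: duplicate gene identifier {dup!r}")
    if df.columns.duplicated().any():
        dup = df.columns[df.columns.duplicated()][0]
        raise ParseError(f"{path}: duplicate sample identifier {dup!r}")
    return ExpressionMatrix(_coerce_numeric(df, path, impute_missing))


def write_expression_matrix(
    m: ExpressionMatrix, path: str | Path, dialect: str = "tsv"
) -> None:
    """Write a matrix so that re-reading it reproduces the values exactly."""
    if dialect not in _SEPS:
        raise ValueError(f"dialect must be one of {sorted(_SEPS)}, got {dialect!r}")
    # shortest-repr float formatting round-trips IEEE doubles bit-exactly
    m.data.to_csv(
        path, sep=_SEPS[dialect], index_label="gene_id",
        float_format=lambda v: repr(float(v)),
    )


def read_labels(path: str | Path) -> SubgroupLabels:
    """Read a two-column (sample_id, subgroup) table; aliases normalized."""
    path = Path(path)
    assignments: dict[str, str] = {}
    lines = [ln for ln in path.read_text().splitlines() if ln.strip() and not ln.startswith("!")]
    for i, line in enumerate(lines):
        parts = [p for p in line.replace(",", "\t").split("\t") if p != ""]
        if len(parts) != 2:
            raise ParseError(f"{path}:{i + 1}: expected 2 columns, got {len(parts)}")
        sample, cls = parts[0].strip(), parts[1].strip()
        if i == 0 and sample.lower() in {"sample", "sample_id", "id"}:
            continue  # optional header
        if sample in assignments:
            raise ParseError(f"{path}: duplicate sample identifier {sample!r}")
        assignments[sample] = normalize_class(cls)
    if not assignments:
        raise ParseError(f"{path}: no label rows found")
    return SubgroupLabels(assignments)


def write_labels(labels: SubgroupLabels, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("sample_id\tsubgroup\n")
        for sample, cls in labels.assignments.items():
            fh.write(f"{sample}\t{cls}\n")


def read_annotation(path: str | Path) -> GeneAnnotation:
    """Read a two-column (probe_id, gene_symbol) table."""
    path = Path(path)
    mapping: dict[str, str] = {}
    lines = [ln for ln in path.read_text().splitlines() if ln.strip() and not ln.startswith("!")]
    for i, line in enumerate(lines):
        parts = [p for p in line.replace(",", "\t").split("\t") if p != ""]
        if len(parts) != 2:
            raise ParseError(f"{path}:{i + 1}: expected 2 columns, got {len(parts)}")
        probe, symbol = parts[0].strip(), parts[1].strip()
        if i == 0 and probe.lower() in {"probe", "probe_id"}:
            continue
        if probe in mapping:
            raise ParseError(f"{path}: duplicate probe identifier {probe!r}")
        mapping[probe] = symbol
    if not mapping:
        raise ParseError(f"{path}: no annotation rows found")
    return GeneAnnotation(mapping)


def read_ct_table(
    path: str | Path,
    reference_gene: str,
    dialect: str = "tsv",
    *,
    max_cycles: float = MAX_CYCLES_DEFAULT,
    undetermined: str = "error",
) -> CtTable:
    """Read a qPCR Ct table (same layout as an expression matrix).

    ``undetermined`` controls wells with no Ct call ("Undetermined"/"NA"):
    ``error`` rejects them, ``censor`` sets them to ``max_cycles`` (the
    no-amplification ceiling).
    """
    if undetermined not in {"error", "censor"}:
        raise ValueError("undetermined policy must be 'error' or 'censor'")
    df = _read_table(path, dialect)
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise ParseError(f"{path}: duplicate gene identifier {dup!r}")
    numeric = df.apply(pd.to_numeric, errors="coerce")
    if numeric.isna().to_numpy().any():
        if undetermined == "error":
            g, s = np.argwhere(numeric.isna().to_numpy())[0]
            raise ParseError(
                f"{path}: undetermined Ct at gene {df.index[g]!r}, sample "
                f"{df.columns[s]!r} (policy=error)"
            )
        numeric = numeric.fillna(max_cycles)
    return CtTable(numeric, reference_gene=reference_gene, max_cycles=max_cycles)


# ---------------------------------------------------------------------------
# matrix transformations
# ---------------------------------------------------------------------------

def collapse_probes(
    m: ExpressionMatrix, ann: GeneAnnotation
) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Collapse probe-level rows to gene symbols.

    When several probes map to one symbol the probe with the highest
    across-sample variance is kept (ties broken by lexicographically smallest
    probe ID); probes without an annotation entry are dropped. Returns the
    collapsed matrix and a per-probe report (probe, symbol, variance, kept).
    """
    mapped = [p for p in m.gene_ids if p in ann.mapping]
    if not mapped:
        raise ValueError("annotation shares no probe with the matrix")
    variances = m.data.var(axis=1, ddof=1)
    best: dict[str, str] = {}  # symbol -> kept probe
    for probe in mapped:
        symbol = ann.mapping[probe]
        cur = best.get(symbol)
        if cur is None:
            best[symbol] = probe
        else:
            v_new, v_cur = variances[probe], variances[cur]
            if v_new > v_cur or (v_new == v_cur and probe < cur):
                best[symbol] = probe
    kept_probes = set(best.values())
    records = []
    for probe in m.gene_ids:
        symbol = ann.mapping.get(probe)
        records.append(
            {
                "probe_id": probe,
                "gene_symbol": symbol if symbol is not None else "",
                "variance": float(variances[probe]),
                "kept": probe in kept_probes,
                "reason": (
                    "kept"
                    if probe in kept_probes
                    else ("unmapped" if symbol is None else "lower_variance")
                ),
            }
        )
    report = pd.DataFrame.from_records(records)
    # preserve the matrix's row order of the kept probes
    order = [p for p in m.gene_ids if p in kept_probes]
    collapsed = m.data.loc[order]
    collapsed.index = [ann.mapping[p] for p in order]
    return ExpressionMatrix(collapsed), report


def align_to_gene_set(
    m: ExpressionMatrix, genes: Sequence[str], policy: str = "strict"
) -> ExpressionMatrix:
    """Subset and reorder a matrix to a requested gene list.

    ``strict`` raises if any requested gene is absent; ``intersect`` keeps
    the present genes (in requested order) and warns about the rest.
    """
    if not genes:
        raise ValueError("requested gene set is empty")
    if policy not in {"strict", "intersect"}:
        raise ValueError("policy must be 'strict' or 'intersect'")
    present = set(m.gene_ids)
    missing = [g for g in genes if g not in present]
    if missing and policy == "strict":
        raise KeyError(f"{missing[0]} not found in matrix (strict alignment)")
    if missing:
        warnings.warn(
            f"{len(missing)} requested gene(s) absent from matrix: {missing}",
            stacklevel=2,
        )
    keep = [g for g in genes if g in present]
    if not keep:
        raise ValueError("no requested gene present in the matrix")
    return ExpressionMatrix(m.data.loc[keep])


# ---------------------------------------------------------------------------
# run manifests
# ---------------------------------------------------------------------------

def write_manifest(
    path: str | Path,
    *,
    inputs: Mapping[str, object],
    config: Mapping[str, object],
    seed: int | None,
) -> None:
    """Write a JSON manifest recording inputs, config, seed and versions."""
    import sklearn
    import scipy
    from . import __version__

    manifest = {
        "inputs": dict(inputs),
        "config": dict(config),
        "seed": seed,
        "versions": {
            "mbsarc": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
            "scipy": scipy.__version__,
            "scikit-learn": sklearn.__version__,
        },
        "timestamp": datetime.now(timezone.utc).isoformat(),
    }
    Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True, default=str) + "\n")
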