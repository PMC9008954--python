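"""Reading, writing and validation of expression matrices, condition labels,
regulatory priors and network edge lists.

All tabular formats are plain tab-separated text:

* expression: genes in rows, samples in columns, header row of sample IDs;
* labels: two columns (sample, condition), optional header;
* prior: two columns (tf, target), optional header;
* networks: three columns (tf, target, efficacy).

Duplicate gene rows (e.g. several probes mapping to one gene) are collapsed
by arithmetic mean at load time; every other malformed input is rejected
with a typed error rather than silently repaired.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

_LABEL_HEADER_NAMES = {"sample", "sample_id", "id"}
_PRIOR_HEADER_NAMES = {"tf", "tf_id", "regulator", "source"}


class ValidationError(ValueError):
    """A structurally invalid dataset, label set, prior or network."""


class ParseError(ValueError):
    """A file that cannot be parsed into the expected tabular shape."""


@dataclass
class ExpressionDataset:
    """A two-condition log2 expression matrix.

    Parameters
    ----------
    values:
        genes x samples data frame of finite log2 expression values.
    condition_of:
        Series mapping each sample ID to one of exactly two condition
        labels; each condition must contain at least three samples.
    """

    values: pd.DataFrame
    condition_of: pd.Series

    def __post_init__(self) -> None:
        if not isinstance(self.values, pd.DataFrame):
            raise ValidationError("expression values must be a DataFrame")
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate gene IDs: {dups[:5]}")
        if self.values.columns.has_duplicates:
            dups = self.values.columns[self.values.columns.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample IDs: {dups[:5]}")
        mat = self.values.to_numpy()
        if not np.issubdtype(mat.dtype, np.number):
            raise ValidationError("expression matrix contains non-numeric values")
        if not np.all(np.isfinite(mat)):
            raise ValidationError("expression matrix contains missing or non-finite values")
        self.condition_of = pd.Series(self.condition_of, dtype=object)
        extra = set(self.condition_of.index) - set(self.values.columns)
        if extra:
            raise ValidationError(f"labels refer to unknown samples: {sorted(extra)[:5]}")
        missing = set(self.values.columns) - set(self.condition_of.index)
        if missing:
            raise ValidationError(f"samples missing a condition label: {sorted(missing)[:5]}")
        # align label order with the matrix column order
        self.condition_of = self.condition_of.reindex(self.values.columns)
        levels = sorted(set(self.condition_of))
        if len(levels) != 2:
            raise ValidationError(f"need exactly 2 condition levels, found {len(levels)}")
        counts = self.condition_of.value_counts()
        if (counts < 3).any():
            raise ValidationError(f"each condition needs >= 3 samples, got {counts.to_dict()}")

    # -- accessors ----------------------------------------------------------

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    @property
    def conditions(self) -> tuple[str, str]:
        """The two condition labels in sorted order."""
        a, b = sorted(set(self.condition_of))
        return a, b

    def samples_in(self, condition: str) -> list[str]:
        return [s for s in self.values.columns if self.condition_of[s] == condition]

    def frame(self, condition: str) -> pd.DataFrame:
        """genes x samples view restricted to one condition."""
        cols = self.samples_in(condition)
        if not cols:
            raise ValidationError(f"unknown condition {condition!r}")
        return self.values[cols]

    def matrix(self, condition: str | None = None) -> np.ndarray:
        if condition is None:
            return self.values.to_numpy()
        return self.frame(condition).to_numpy()


@dataclass
class RegulatoryPrior:
    """Candidate TF -> target pairs defining the search space for GRN fitting."""

    pairs: set[tuple[str, str]]
    n_self_dropped: int = 0
    tfs: set[str] = field(init=False)

    def __post_init__(self) -> None:
        for tf, tg in self.pairs:
            if tf == tg:
                raise ValidationError(f"self-regulation pair in prior: {tf}")
        self.tfs = {tf for tf, _ in self.pairs}

    def regulators_of(self, target: str) -> list[str]:
        return sorted(tf for tf, tg in self.pairs if tg == target)


def load_expression(matrix_path, labels_path) -> ExpressionDataset:
    """Load and validate an expression matrix plus its condition labels.

    Duplicate gene rows are collapsed by arithmetic mean (keeping the first
    occurrence's position); any other inconsistency raises a typed error.
    """
    try:
        values = pd.read_csv(matrix_path, sep="\t", index_col=0)
    except Exception as exc:  # noqa: BLE001 - normalise parser failures
        raise ParseError(f"cannot parse expression matrix {matrix_path}: {exc}") from exc
    if values.shape[1] == 0:
        raise ParseError(f"expression matrix {matrix_path} has no sample columns")
    values.index = values.index.astype(str)
    values.columns = values.columns.astype(str)
    non_numeric = [c for c in values.columns if not np.issubdtype(values[c].dtype, np.number)]
    if non_numeric:
        raise ParseError(f"non-numeric expression values in columns {non_numeric[:5]}")
    if values.index.has_duplicates:
        n_before = len(values)
        order = values.index.drop_duplicates()
        values = values.groupby(level=0, sort=False).mean().loc[order]
        logger.warning("collapsed %d duplicate gene rows by mean", n_before - len(values))
    labels = _read_two_column(labels_path, header_names=_LABEL_HEADER_NAMES)
    if labels.iloc[:, 0].duplicated().any():
        raise ValidationError(f"duplicate sample IDs in labels file {labels_path}")
    condition_of = pd.Series(
        labels.iloc[:, 1].to_numpy(), index=labels.iloc[:, 0].to_numpy(), dtype=object
    )
    return ExpressionDataset(values=values, condition_of=condition_of)


def load_prior(path) -> RegulatoryPrior:
    """Load a two-column TF -> target prior; self-pairs are dropped with a warning."""
    table = _read_two_column(path, header_names=_PRIOR_HEADER_NAMES)
    pairs: set[tuple[str, str]] = set()
    n_self = 0
    for tf, tg in zip(table.iloc[:, 0], table.iloc[:, 1]):
        tf, tg = str(tf), str(tg)
        if tf == tg:
            n_self += 1
            continue
        pairs.add((tf, tg))
    if n_self:
        logger.warning("dropped %d self-regulation pairs from prior %s", n_self, path)
    if not pairs:
        raise ParseError(f"prior {path} contains no usable TF-target pairs")
    return RegulatoryPrior(pairs=pairs, n_self_dropped=n_self)


def _read_two_column(path, header_names: set[str]) -> pd.DataFrame:
    try:
        table = pd.read_csv(path, sep="\t", header=None, dtype=str, skip_blank_lines=True)
    except Exception as exc:  # noqa: BLE001
        raise ParseError(f"cannot parse {path}: {exc}") from exc
    if table.shape[1] < 2:
        raise ParseError(f"{path}: expected two tab-separated columns, found {table.shape[1]}")
    if table.shape[1] > 2:
        extra = table.iloc[:, 2:].notna().any().any()
        if extra:
            raise ParseError(f"{path}: expected two columns, found {table.shape[1]}")
        table = table.iloc[:, :2]
    if table.isna().any().any():
        raise ParseError(f"{path}: incomplete rows (missing fields)")
    if len(table) and str(table.iloc[0, 0]).strip().lower() in header_names:
        table = table.iloc[1:]
    if not len(table):
        raise ParseError(f"{path}: no data rows")
    return table.reset_index(drop=True)


# -- network edge lists -----------------------------------------------------


def write_network(grn, path) -> None:
    """Write a GRN as a (tf, target, efficacy) edge-list TSV.

    Efficacies are written with ``repr`` so a read-back reproduces the GRN
    bit for bit.
    """
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("tf\ttarget\tefficacy\n")
        for (tf, tg) in sorted(grn.links):
            fh.write(f"{tf}\t{tg}\t{grn.links[(tf, tg)]!r}\n")


def read_network(path, condition: str = ""):
    """Read an edge-list TSV written by :func:`write_network` into a GRN."""
    from .grn import GRN  # local import to avoid a cycle

    links: dict[tuple[str, str], float] = {}
    with open(path, encoding="utf-8") as fh:
        header = fh.readline()
        if not header.startswith("tf\ttarget"):
            raise ParseError(f"{path}: missing 'tf\\ttarget\\tefficacy' header")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise ParseError(f"{path}:{lineno}: expected 3 columns")
            try:
                eff = float(parts[2])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-numeric efficacy {parts[2]!r}") from exc
            links[(parts[0], parts[1])] = eff
    return GRN(condition=condition, links=links)


def write_graphml(grn, path) -> None:
    """GraphML export of a GRN for visualization tools."""
    import networkx as nx

    g = nx.DiGraph(condition=grn.condition)
    for (tf, tg), eff in grn.links.items():
        g.add_edge(tf, tg, efficacy=float(eff))
    nx.write_graphml(g, path)


def write_expression(ds: ExpressionDataset, matrix_path, labels_path) -> None:
    """Write an ExpressionDataset in the load_expression TSV formats."""
    out = ds.values.copy()
    out.index.name = "gene"
    out.to_csv(matrix_path, sep="\t")
    with open(labels_path, "w", encoding="utf-8") as fh:
        fh.write("sample\tcondition\n")
        for s in ds.samples:
            fh.write(f"{s}\t{ds.condition_of[s]}\n")


def write_prior(prior: RegulatoryPrior, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("tf\ttarget\n")
        for tf, tg in sorted(prior.pairs):
            fh.write(f"{tf}\t{tg}\n")


def write_table(table: pd.DataFrame, path) -> None:
    """Write an analysis output table as TSV (no index, stable formatting)."""
    table.to_csv(path, sep="\t", index=False, float_format="%.10g")
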