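"""Core containers and text-format I/O for two-group expression data.

The central object is :class:`ExpressionDataset`: a features × samples matrix
of (post-normalization, strictly positive) expression values together with a
two-level group assignment mapping every sample to ``control`` or
``experiment``.  Selection methods produce :class:`ScoreTable` objects — one
score, 1-based rank and regulation direction per feature — and enrichment
consumes :class:`GeneSetCollection` objects read from GMT files.

All on-disk formats are plain delimited text: expression matrices as TSV/CSV
(or GCT 1.2) with feature IDs in the first column and sample IDs in the
header, labels as a two-column table, gene sets as standard GMT.
"""

from __future__ import annotations

import csv
import io
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

CONTROL = "control"
EXPERIMENT = "experiment"

#: accepted spellings for each group in label files (case-insensitive)
_GROUP_ALIASES = {
    "control": CONTROL, "ctr": CONTROL, "ctrl": CONTROL, "0": CONTROL,
    "experiment": EXPERIMENT, "exp": EXPERIMENT, "case": EXPERIMENT, "1": EXPERIMENT,
}

#: minimum group size required by the variance-based statistics downstream
MIN_GROUP_SIZE = 3


class DataError(ValueError):
    """Raised when an input violates the dataset contract."""


@dataclass
class ExpressionDataset:
    """Features × samples expression matrix with a two-level group factor.

    Parameters
    ----------
    values
        Real matrix of shape (n_features, n_samples); no missing values.
    feature_ids, sample_ids
        Unique identifier lists matching the matrix dimensions.
    groups
        Mapping sample_id -> ``"control"`` | ``"experiment"`` covering every
        sample; both groups must be non-empty.
    """

    values: np.ndarray
    feature_ids: list[str]
    sample_ids: list[str]
    groups: dict[str, str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.feature_ids = [str(f) for f in self.feature_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        if self.values.ndim != 2:
            raise DataError("expression matrix must be 2-dimensional")
        nf, ns = self.values.shape
        if nf != len(self.feature_ids) or ns != len(self.sample_ids):
            raise DataError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.feature_ids)} features x {len(self.sample_ids)} samples"
            )
        if len(set(self.feature_ids)) != nf:
            raise DataError("duplicate feature IDs")
        if len(set(self.sample_ids)) != ns:
            raise DataError("duplicate sample IDs")
        missing = [s for s in self.sample_ids if s not in self.groups]
        if missing:
            raise DataError(f"unlabeled sample(s): {', '.join(missing[:5])}")
        bad = {g for g in self.groups.values()} - {CONTROL, EXPERIMENT}
        if bad:
            raise DataError(f"unknown group label(s): {sorted(bad)}")
        if not np.isfinite(self.values).all():
            raise DataError("expression matrix contains missing or non-finite values")
        if self.n_control == 0 or self.n_experiment == 0:
            raise DataError("both groups must be non-empty")

    # -- group views -------------------------------------------------------

    @property
    def group_labels(self) -> np.ndarray:
        """Per-sample group labels in sample order."""
        return np.array([self.groups[s] for s in self.sample_ids])

    @property
    def y(self) -> np.ndarray:
        """Binary group indicator in sample order (experiment = 1)."""
        return (self.group_labels == EXPERIMENT).astype(int)

    @property
    def control_mask(self) -> np.ndarray:
        return self.group_labels == CONTROL

    @property
    def experiment_mask(self) -> np.ndarray:
        return self.group_labels == EXPERIMENT

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def n_control(self) -> int:
        return int(np.count_nonzero(self.control_mask))

    @property
    def n_experiment(self) -> int:
        return int(np.count_nonzero(self.experiment_mask))

    def feature_index(self, feature_id: str) -> int:
        try:
            return self.feature_ids.index(feature_id)
        except ValueError:
            raise KeyError(f"unknown feature ID: {feature_id}") from None

    def subset_samples(self, mask: np.ndarray) -> "ExpressionDataset":
        """Dataset restricted to the samples where ``mask`` is True."""
        mask = np.asarray(mask, dtype=bool)
        kept = [s for s, m in zip(self.sample_ids, mask) if m]
        return ExpressionDataset(
            values=self.values[:, mask],
            feature_ids=list(self.feature_ids),
            sample_ids=kept,
            groups={s: self.groups[s] for s in kept},
        )

    def subset_features(self, feature_ids: list[str]) -> "ExpressionDataset":
        idx = [self.feature_index(f) for f in feature_ids]
        return ExpressionDataset(
            values=self.values[idx, :],
            feature_ids=list(feature_ids),
            sample_ids=list(self.sample_ids),
            groups=dict(self.groups),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.feature_ids, columns=self.sample_ids)


@dataclass
class ScoreTable:
    """Per-feature score, 1-based rank and regulation direction for one method.

    Ranks are assigned by descending score; ties receive the average of the
    tied positions, so ranks always sum to n(n+1)/2.  ``direction`` is ``up``
    (over-expressed in the experiment group), ``down`` or ``none``.
    """

    method: str
    feature_ids: list[str]
    scores: np.ndarray
    ranks: np.ndarray = field(default=None)  # type: ignore[assignment]
    directions: list[str] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        n = len(self.feature_ids)
        if self.scores.shape != (n,):
            raise DataError("scores length does not match feature list")
        if self.ranks is None:
            self.ranks = rank_descending(self.scores)
        else:
            self.ranks = np.asarray(self.ranks, dtype=float)
        if self.directions is None:
            self.directions = ["none"] * n
        if len(self.directions) != n:
            raise DataError("directions length does not match feature list")

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    def top(self, k: int) -> list[str]:
        """The k best-ranked feature IDs (rank ascending, ties by input order)."""
        order = np.argsort(self.ranks, kind="stable")[:k]
        return [self.feature_ids[i] for i in order]

    def rank_of(self, feature_id: str) -> float:
        return float(self.ranks[self.feature_ids.index(feature_id)])

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "feature_id": self.feature_ids,
                "score": self.scores,
                "rank": self.ranks,
                "direction": self.directions,
            }
        )
        return df.sort_values("rank", kind="stable").reset_index(drop=True)


def rank_descending(scores: np.ndarray) -> np.ndarray:
    """1-based ranks, highest score first; ties get the average tied position."""
    from scipy.stats import rankdata

    scores = np.asarray(scores, dtype=float)
    return rankdata(-scores, method="average")


@dataclass
class GeneSetCollection:
    """Named gene sets over a symbol universe."""

    sets: list[tuple[str, frozenset[str]]]
    universe: frozenset[str] = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        names = [n for n, _ in self.sets]
        if len(set(names)) != len(names):
            raise DataError("duplicate gene-set names")
        if self.universe is None:
            u: set[str] = set()
            for _, genes in self.sets:
                u |= genes
            self.universe = frozenset(u)
        else:
            self.universe = frozenset(self.universe)

    def __len__(self) -> int:
        return len(self.sets)

    def restrict(self, universe: set[str]) -> "GeneSetCollection":
        """Intersect every set (and the universe) with ``universe``."""
        uni = frozenset(universe)
        kept = [(n, genes & uni) for n, genes in self.sets]
        return GeneSetCollection(sets=[(n, g) for n, g in kept if g], universe=uni)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def _sniff_delimiter(sample: str) -> str:
    try:
        return csv.Sniffer().sniff(sample, delimiters="\t,;").delimiter
    except csv.Error:
        return "\t"


def read_labels(path) -> dict[str, str]:
    """Read a two-column sample_id → group table (header optional).

    Accepts the aliases control/ctr/ctrl/0 and experiment/exp/case/1.
    """
    groups: dict[str, str] = {}
    with open(path, "rt", encoding="utf-8") as fh:
        text = fh.read()
    delim = _sniff_delimiter(text.splitlines()[0]) if text.strip() else "\t"
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = [p.strip() for p in line.split(delim)]
        if len(parts) < 2:
            raise DataError(f"labels line {lineno}: expected 2 columns")
        sid, raw = parts[0], parts[1].lower()
        if lineno == 1 and raw in {"group", "label", "class"}:
            continue  # header row
        if raw not in _GROUP_ALIASES:
            raise DataError(f"labels line {lineno}: unknown group {parts[1]!r}")
        if sid in groups:
            raise DataError(f"duplicate sample ID in labels: {sid}")
        groups[sid] = _GROUP_ALIASES[raw]
    if not groups:
        raise DataError("empty labels file")
    return groups


def read_expression(path, labels_path, *, delimiter: str | None = None,
                    transpose: bool = False) -> ExpressionDataset:
    """Read a delimited expression matrix plus its label file.

    The matrix has feature IDs in the first column and a header row of sample
    IDs (GCT 1.2 is detected from its ``#1.2`` first line).  Every sample must
    be labeled; each group needs at least :data:`MIN_GROUP_SIZE` samples so
    that within-group variances are estimable.
    """
    with open(path, "rt", encoding="utf-8") as fh:
        first = fh.readline()
    if first.startswith("#1.2"):
        df = _read_gct(path)
    else:
        delim = delimiter or _sniff_delimiter(first)
        df = pd.read_csv(path, sep=delim, index_col=0, float_precision="round_trip")
    if transpose:
        df = df.T
    if df.isna().any().any():
        raise DataError("expression matrix contains missing cells")
    try:
        values = df.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise DataError(f"non-numeric cell in expression matrix: {exc}") from None

    groups_all = read_labels(labels_path)
    sample_ids = [str(s) for s in df.columns]
    missing = [s for s in sample_ids if s not in groups_all]
    if missing:
        raise DataError(f"unlabeled sample(s): {', '.join(missing[:5])}")
    groups = {s: groups_all[s] for s in sample_ids}
    ds = ExpressionDataset(
        values=values,
        feature_ids=[str(f) for f in df.index],
        sample_ids=sample_ids,
        groups=groups,
    )
    if ds.n_control < MIN_GROUP_SIZE or ds.n_experiment < MIN_GROUP_SIZE:
        raise DataError(
            f"each group needs >= {MIN_GROUP_SIZE} samples "
            f"(got {ds.n_control} control, {ds.n_experiment} experiment)"
        )
    return ds


def _read_gct(path) -> pd.DataFrame:
    """GCT 1.2: '#1.2' line, 'n_rows\\tn_cols' line, then Name/Description + data."""
    with open(path, "rt", encoding="utf-8") as fh:
        version = fh.readline().strip()
        if not version.startswith("#1.2"):
            raise DataError("not a GCT 1.2 file")
        dims = fh.readline().split()
        if len(dims) < 2:
            raise DataError("malformed GCT dimensions line")
        n_rows, n_cols = int(dims[0]), int(dims[1])
        df = pd.read_csv(fh, sep="\t", index_col=0)
    df = df.drop(columns=["Description"], errors="ignore")
    if df.shape != (n_rows, n_cols):
        raise DataError(
            f"GCT dimensions line says {n_rows}x{n_cols}, data are {df.shape}"
        )
    return df


def write_expression(dataset: ExpressionDataset, path, labels_path=None) -> None:
    """Write the matrix as TSV; optionally write the label file alongside."""
    # repr gives the shortest exact round-trip decimal for each value
    dataset.to_frame().to_csv(
        path, sep="\t", index_label="feature_id",
        float_format=lambda x: repr(float(x)),
    )
    if labels_path is not None:
        with open(labels_path, "wt", encoding="utf-8") as fh:
            for s in dataset.sample_ids:
                fh.write(f"{s}\t{dataset.groups[s]}\n")


def write_scores(table: ScoreTable, path, *, header_comment: str | None = None) -> None:
    """Write a score table as TSV (feature_id, score, rank, direction), rank order."""
    buf = io.StringIO()
    if header_comment:
        buf.write(f"# {header_comment}\n")
    table.to_frame().to_csv(buf, sep="\t", index=False, float_format="%.12g")
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write(buf.getvalue())


def read_scores(path) -> ScoreTable:
    df = pd.read_csv(path, sep="\t", comment="#")
    return ScoreTable(
        method="file",
        feature_ids=[str(f) for f in df["feature_id"]],
        scores=df["score"].to_numpy(dtype=float),
        ranks=df["rank"].to_numpy(dtype=float),
        directions=[str(d) for d in df["direction"]],
    )


def read_gmt(path) -> GeneSetCollection:
    """Read a GMT file: ``name TAB description TAB gene TAB gene ...``.

    Duplicate genes within a line collapse (set semantics); lines whose gene
    list is empty are dropped with a warning; a line with fewer than two tabs
    is malformed.
    """
    sets: list[tuple[str, frozenset[str]]] = []
    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise DataError(f"GMT line {lineno}: expected name, description, genes")
            name = parts[0]
            genes = frozenset(g.strip() for g in parts[2:] if g.strip())
            if not genes:
                warnings.warn(f"GMT line {lineno}: empty set {name!r} dropped")
                continue
            sets.append((name, genes))
    return GeneSetCollection(sets=sets)


def read_probe_map(path) -> dict[str, str]:
    """Two-column probe → gene-symbol TSV (header optional)."""
    mapping: dict[str, str] = {}
    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = [p.strip() for p in line.rstrip("\n").split("\t")]
            if len(parts) < 2:
                raise DataError(f"probe map line {lineno}: expected 2 columns")
            if lineno == 1 and parts[1].lower() in {"symbol", "gene", "gene_symbol"}:
                continue
            mapping[parts[0]] = parts[1]
    return mapping
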