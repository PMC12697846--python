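"""Readers/writers for count tables, metadata, sequences, trees and configs,
plus rarefaction preprocessing.

Conventions: count tables are TSV with taxa as rows and samples as columns;
metadata is TSV with at least ``sample_id`` and ``habitat`` columns; counts are
integers — relative abundances are always derived, never stored in files.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, fields
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO

logger = logging.getLogger(__name__)

PER_HABITAT_MIN = "per-habitat-min"


class ValidationError(ValueError):
    """Input data violates a structural invariant."""


@dataclass
class CountTable:
    """Taxon x sample integer abundance matrix with a sample->habitat mapping.

    Parameters
    ----------
    counts
        DataFrame indexed by taxon id, columns are sample ids, values are
        non-negative integers.
    habitat_of
        Series mapping every sample id to its habitat label.
    """

    counts: pd.DataFrame
    habitat_of: pd.Series

    def __post_init__(self) -> None:
        counts = self.counts
        if counts.index.has_duplicates:
            raise ValidationError("duplicate taxon ids in count table")
        if counts.columns.has_duplicates:
            raise ValidationError("duplicate sample ids in count table")
        missing = [s for s in counts.columns if s not in self.habitat_of.index]
        if missing:
            raise ValidationError(f"samples without habitat label: {missing}")
        vals = counts.to_numpy()
        if vals.size:
            if np.issubdtype(vals.dtype, np.floating):
                if not np.all(np.mod(vals, 1) == 0):
                    raise ValidationError("counts must be integral")
                counts = counts.astype(np.int64)
            if (counts.to_numpy() < 0).any():
                raise ValidationError("counts must be non-negative")
            object.__setattr__(self, "counts", counts.astype(np.int64))
        # keep only the mapping for samples in the table, in column order
        object.__setattr__(
            self, "habitat_of", self.habitat_of.reindex(counts.columns)
        )
        if self.habitat_of.isna().any() or (self.habitat_of == "").any():
            raise ValidationError("every sample needs a non-empty habitat label")

    # -- basic accessors -------------------------------------------------
    @property
    def taxon_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def habitats(self) -> list[str]:
        """Habitat labels in order of first appearance among samples."""
        return list(dict.fromkeys(self.habitat_of))

    def samples_in(self, habitat: str) -> list[str]:
        return [s for s in self.counts.columns if self.habitat_of[s] == habitat]

    def depths(self) -> pd.Series:
        """Per-sample total read counts (column sums)."""
        return self.counts.sum(axis=0)

    def relative_abundance(self) -> pd.DataFrame:
        """Counts divided by their sample's total; zero-depth samples give 0."""
        tot = self.counts.sum(axis=0).replace(0, np.nan)
        return self.counts.div(tot, axis=1).fillna(0.0)

    def copy(self) -> "CountTable":
        return CountTable(self.counts.copy(), self.habitat_of.copy())

    # -- persistence -----------------------------------------------------
    def write(self, counts_path: str | Path, metadata_path: str | Path) -> None:
        df = self.counts.copy()
        df.index.name = "taxon_id"
        df.to_csv(counts_path, sep="\t")
        meta = pd.DataFrame(
            {"sample_id": self.sample_ids, "habitat": self.habitat_of.values}
        )
        meta.to_csv(metadata_path, sep="\t", index=False)


def read_count_table(path: str | Path, metadata_path: str | Path) -> CountTable:
    """Read a taxa-by-samples TSV and its sample metadata into a CountTable.

    Every sample column must appear in the metadata; counts must be
    non-negative integers.
    """
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise ValidationError(f"malformed count table {path}: {exc}") from exc
    meta = read_sample_metadata(metadata_path)
    unknown = [s for s in df.columns if s not in meta.index]
    if unknown:
        raise ValidationError(f"samples missing from metadata: {unknown}")
    if df.size and not np.issubdtype(df.to_numpy().dtype, np.number):
        raise ValidationError("count table contains non-numeric cells")
    return CountTable(df, meta["habitat"])


def read_sample_metadata(path: str | Path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t", dtype=str)
    if "sample_id" not in meta.columns or "habitat" not in meta.columns:
        raise ValidationError("metadata needs 'sample_id' and 'habitat' columns")
    if meta["sample_id"].duplicated().any():
        raise ValidationError("duplicate sample ids in metadata")
    return meta.set_index("sample_id")


# ---------------------------------------------------------------------------
# Rarefaction
# ---------------------------------------------------------------------------

def rarefy(
    table: CountTable,
    depth: int | str = PER_HABITAT_MIN,
    seed: int = 0,
) -> CountTable:
    """Subsample each sample, without replacement, to a common depth.

    ``depth`` may be a positive integer (samples shallower than it are dropped
    with a warning) or ``"per-habitat-min"``: each habitat's samples are
    rarefied to the minimum sequencing depth within that habitat, so no sample
    is dropped.  The draw is a multivariate hypergeometric sample per column;
    identical seeds give identical output.
    """
    if isinstance(depth, str):
        if depth != PER_HABITAT_MIN:
            raise ValueError(f"unknown depth mode {depth!r}")
    elif depth <= 0:
        raise ValueError("rarefaction depth must be positive")

    col_sums = table.counts.sum(axis=0)
    targets: dict[str, int] = {}
    if depth == PER_HABITAT_MIN:
        for hab in table.habitats:
            samples = table.samples_in(hab)
            hab_min = int(col_sums[samples].min())
            if hab_min <= 0:
                raise ValueError(f"habitat {hab!r} has an empty sample")
            for s in samples:
                targets[s] = hab_min
    else:
        for s in table.sample_ids:
            if col_sums[s] >= depth:
                targets[s] = int(depth)
            else:
                logger.warning(
                    "dropping sample %s (depth %d < target %d)",
                    s, col_sums[s], depth,
                )
    if not targets:
        raise ValueError("all samples fall below the rarefaction depth")

    rng = np.random.default_rng(seed)
    out = {}
    for s in table.sample_ids:  # fixed order => deterministic
        if s not in targets:
            continue
        col = table.counts[s].to_numpy()
        want = targets[s]
        if col.sum() == want:
            out[s] = col
        else:
            out[s] = rng.multivariate_hypergeometric(col, want)
    kept = list(out)
    new_counts = pd.DataFrame(out, index=table.counts.index, columns=kept)
    return CountTable(new_counts, table.habitat_of[kept])


# ---------------------------------------------------------------------------
# Function tables, sequences, trees, configs
# ---------------------------------------------------------------------------

def read_function_table(path: str | Path):
    """Read a two-column (taxon_id, function_id) TSV into a FunctionTable.

    Duplicate rows collapse to one incidence.  Returns an empty table, with a
    warning, for a header-only file.
    """
    from habniche.functional import FunctionTable

    df = pd.read_csv(path, sep="\t", dtype=str)
    if list(df.columns[:2]) != ["taxon_id", "function_id"]:
        raise ValidationError(
            "function table needs 'taxon_id' and 'function_id' columns"
        )
    if df.isna().any().any():
        raise ValidationError("function table has incomplete rows")
    if df.empty:
        logger.warning("function table %s has no rows", path)
    pairs = set(zip(df["taxon_id"], df["function_id"]))
    carriers: dict[str, set[str]] = {}
    for t, f in pairs:
        carriers.setdefault(t, set()).add(f)
    return FunctionTable(carriers)


def write_function_table(ftable, path: str | Path) -> None:
    rows = [
        (t, f)
        for t in sorted(ftable.carriers)
        for f in sorted(ftable.carriers[t])
    ]
    pd.DataFrame(rows, columns=["taxon_id", "function_id"]).to_csv(
        path, sep="\t", index=False
    )


def read_fasta(path: str | Path) -> dict[str, str]:
    """FASTA -> ordered {id: sequence}; duplicate ids are an error."""
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seqs:
            raise ValidationError(f"duplicate FASTA id {rec.id!r}")
        seqs[rec.id] = str(rec.seq).upper()
    return seqs


def write_fasta(seqs: dict[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n{seq}\n")


def read_newick(path: str | Path) -> dendropy.Tree:
    """Read a Newick tree, preserving underscores in labels."""
    return dendropy.Tree.get(
        path=str(path), schema="newick", preserve_underscores=True
    )


def write_newick(tree: dendropy.Tree, path: str | Path) -> None:
    tree.write(path=str(path), schema="newick", unquoted_underscores=True)


@dataclass
class RunConfig:
    """Run-level knobs shared by the CLI subcommands."""

    rarefaction_depth: int | str = PER_HABITAT_MIN
    presence_threshold: int = 1
    random_seed: int = 0
    nonnative_quantile: float = 0.5
    random_removal_replicates: int = 100
    otu_identity: float = 0.97
    log_base: str = "natural"  # or "10"

    def __post_init__(self) -> None:
        if isinstance(self.rarefaction_depth, int) and self.rarefaction_depth <= 0:
            raise ValueError("rarefaction_depth must be positive")
        if self.presence_threshold < 0:
            raise ValueError("presence_threshold must be >= 0")
        if not 0 < self.nonnative_quantile < 1:
            raise ValueError("nonnative_quantile must be in (0,1)")
        if self.random_removal_replicates <= 0:
            raise ValueError("random_removal_replicates must be positive")
        if not 0 < self.otu_identity <= 1:
            raise ValueError("otu_identity must be in (0,1]")
        if self.log_base not in ("natural", "10"):
            raise ValueError("log_base must be 'natural' or '10'")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        return cls(**{k: v for k, v in raw.items() if k in known})


def read_cycle_sets(path: str | Path) -> dict[str, list[str]]:
    """YAML mapping of function-set name (C/N/P/S...) -> list of function ids."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return {str(k): [str(x) for x in v] for k, v in raw.items()}


def write_cycle_sets(sets: dict[str, list[str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump({k: list(v) for k, v in sets.items()}, fh, sort_keys=True)
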