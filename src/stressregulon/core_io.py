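"""Data model and readers/writers for the pipeline's file formats.

The pipeline operates on three kinds of objects:

* :class:`CountExperiment` — an integer gene × sample read-count matrix plus a
  sample design table (genotype, stress experiment, time-point, replicate).
* :class:`AnnotationMap` — a many-to-many term → gene-set map (TF binding-site
  targets, network modules, or generic annotations), optionally with a
  term → family map.
* :class:`GeneSet` — a named, optionally directed set of gene identifiers.

Formats are deliberately plain: TSV or MatrixMarket for counts, headered TSV
for the design and side tables, GMT for gene sets, YAML for configuration and
JSON for the run manifest.  Gene and sample identifiers are opaque strings.
All validation happens at read time so downstream stages can assume
well-formed objects.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.io

VALID_TIMEPOINTS = ("control", "early", "late")
DESIGN_COLUMNS = ("sample", "genotype", "stress", "timepoint", "replicate")

# canonical synonyms accepted in design files
_TIMEPOINT_ALIASES = {
    "control": "control", "con": "control", "ctrl": "control", "c": "control",
    "early": "early", "e": "early",
    "late": "late", "l": "late",
}


class FormatError(ValueError):
    """Malformed input file (bad header, negative count, short GMT line...)."""


class ValidationError(ValueError):
    """Structurally valid file whose content violates a pipeline invariant."""


@dataclass
class GeneSet:
    """A named gene set with an optional regulation direction."""

    name: str
    genes: frozenset[str]
    direction: str = "none"  # one of {"up", "down", "none"}

    def __post_init__(self) -> None:
        if self.direction not in ("up", "down", "none"):
            raise ValidationError(
                f"GeneSet {self.name!r}: direction must be up/down/none, "
                f"got {self.direction!r}"
            )
        self.genes = frozenset(self.genes)

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, gene: str) -> bool:
        return gene in self.genes


@dataclass
class AnnotationMap:
    """Term → target-gene map with an optional term → family map.

    Terms may be TF names (targets = genes with a binding site), network
    module names (targets = module members) or generic annotation IDs.
    """

    targets: dict[str, frozenset[str]]
    family: dict[str, str] | None = None

    def __post_init__(self) -> None:
        self.targets = {t: frozenset(g) for t, g in self.targets.items()}
        for term, genes in self.targets.items():
            if not genes:
                raise ValidationError(f"term {term!r} has an empty target set")
        if self.family is not None:
            missing = set(self.targets) - set(self.family)
            if missing:
                raise ValidationError(
                    f"family map does not cover terms: {sorted(missing)[:5]}"
                )

    @property
    def terms(self) -> list[str]:
        return list(self.targets)

    def __len__(self) -> int:
        return len(self.targets)

    def restricted_to(self, universe: Iterable[str]) -> "AnnotationMap":
        """Intersect every target set with *universe*; drop emptied terms."""
        uni = frozenset(universe)
        kept = {t: g & uni for t, g in self.targets.items() if g & uni}
        fam = None
        if self.family is not None:
            fam = {t: self.family[t] for t in kept}
        return AnnotationMap(targets=kept, family=fam)


@dataclass
class CountExperiment:
    """Integer read-count matrix with its sample design.

    ``counts`` is genes × samples; ``design`` is indexed by sample and has
    columns genotype / stress / timepoint / replicate.  The constructor
    enforces every invariant the downstream stages rely on.
    """

    genes: list[str]
    samples: list[str]
    counts: np.ndarray
    design: pd.DataFrame

    def __post_init__(self) -> None:
        self.genes = list(self.genes)
        self.samples = list(self.samples)
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.genes), len(self.samples)):
            raise ValidationError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.genes)} genes x {len(self.samples)} samples"
            )
        if not np.issubdtype(self.counts.dtype, np.integer):
            if not np.all(np.equal(np.mod(self.counts, 1), 0)):
                raise FormatError("counts must be integral")
            self.counts = self.counts.astype(np.int64)
        if (self.counts < 0).any():
            g = self.genes[int(np.argwhere(self.counts < 0)[0][0])]
            raise FormatError(f"negative count in row for gene {g!r}")
        if len(set(self.genes)) != len(self.genes):
            dupes = pd.Index(self.genes)
            dupe = dupes[dupes.duplicated()][0]
            raise FormatError(f"duplicate gene ID {dupe!r}")
        if len(set(self.samples)) != len(self.samples):
            raise FormatError("duplicate sample IDs in counts")
        validate_design(self.design, self.samples)
        # align design row order to sample order
        self.design = self.design.loc[self.samples]

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def sample_mask(
        self,
        genotype: str | None = None,
        stress: str | None = None,
        timepoint: str | None = None,
    ) -> np.ndarray:
        """Boolean mask over samples matching the given design labels."""
        mask = np.ones(self.n_samples, dtype=bool)
        if genotype is not None:
            mask &= (self.design["genotype"] == genotype).to_numpy()
        if stress is not None:
            mask &= (self.design["stress"] == stress).to_numpy()
        if timepoint is not None:
            mask &= (self.design["timepoint"] == timepoint).to_numpy()
        return mask

    def subset_genes(self, keep: Sequence[str] | np.ndarray) -> "CountExperiment":
        if isinstance(keep, np.ndarray) and keep.dtype == bool:
            idx = np.flatnonzero(keep)
            genes = [self.genes[i] for i in idx]
        else:
            pos = {g: i for i, g in enumerate(self.genes)}
            idx = np.array([pos[g] for g in keep], dtype=int)
            genes = list(keep)
        return CountExperiment(
            genes=genes,
            samples=self.samples,
            counts=self.counts[idx, :],
            design=self.design,
        )


def validate_design(design: pd.DataFrame, samples: Sequence[str]) -> None:
    """Check a design table against the counted samples.

    Raises :class:`ValidationError` listing offending samples if the design
    does not cover every counted sample, has unknown time-point labels, or
    repeats a (genotype, stress, timepoint, replicate) tuple.
    """
    for col in ("genotype", "stress", "timepoint", "replicate"):
        if col not in design.columns:
            raise ValidationError(f"design is missing column {col!r}")
    missing = [s for s in samples if s not in design.index]
    if missing:
        raise ValidationError(f"design missing counted samples: {missing}")
    bad_tp = sorted(set(design["timepoint"]) - set(VALID_TIMEPOINTS))
    if bad_tp:
        raise ValidationError(f"unknown timepoint labels: {bad_tp}")
    key = design.loc[list(samples), ["genotype", "stress", "timepoint", "replicate"]]
    if key.duplicated().any():
        dup = key[key.duplicated()].iloc[0]
        raise ValidationError(
            "duplicate design tuple "
            f"({dup['genotype']}, {dup['stress']}, {dup['timepoint']}, "
            f"{dup['replicate']})"
        )


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def read_counts_matrix(path: str | Path, format: str = "tsv"):
    """Read a count matrix; returns ``(genes, samples, counts)``.

    ``tsv``: header row of sample IDs, first column of gene IDs.
    ``mtx``: MatrixMarket file ``<path>``, with row labels in
    ``<path>.rows.txt`` and column labels in ``<path>.cols.txt`` (one per
    line).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "tsv":
        df = pd.read_csv(path, sep="\t", index_col=0)
        if df.index.has_duplicates:
            dupe = df.index[df.index.duplicated()][0]
            raise FormatError(f"duplicate gene ID {dupe!r} in {path}")
        values = df.to_numpy()
        if values.size and not np.issubdtype(values.dtype, np.number):
            raise FormatError(f"non-numeric entries in {path}")
        if values.size and (values < 0).any():
            row = df.index[int(np.argwhere((values < 0).any(axis=1))[0][0])]
            raise FormatError(f"negative count at gene {row!r} in {path}")
        if values.size and not np.all(np.mod(values, 1) == 0):
            row = df.index[int(np.argwhere((np.mod(values, 1) != 0).any(axis=1))[0][0])]
            raise FormatError(f"non-integer count at gene {row!r} in {path}")
        return list(df.index.astype(str)), list(df.columns.astype(str)), values.astype(np.int64)
    if format == "mtx":
        mat = scipy.io.mmread(path)
        counts = np.asarray(mat.todense() if hasattr(mat, "todense") else mat)
        genes = Path(str(path) + ".rows.txt").read_text().split()
        samples = Path(str(path) + ".cols.txt").read_text().split()
        if counts.shape != (len(genes), len(samples)):
            raise FormatError(
                f"matrix shape {counts.shape} does not match label sidecars"
            )
        if (counts < 0).any():
            raise FormatError(f"negative count in {path}")
        if not np.all(np.mod(counts, 1) == 0):
            raise FormatError(f"non-integer count in {path}")
        return genes, samples, counts.astype(np.int64)
    raise ValueError(f"unknown count format {format!r}")


def read_design(path: str | Path) -> pd.DataFrame:
    """Read and validate a sample design TSV (sample/genotype/stress/timepoint/replicate)."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={"sample": str, "genotype": str, "stress": str})
    missing = [c for c in DESIGN_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"design {path} missing columns {missing}")
    tp = df["timepoint"].astype(str).str.lower().map(_TIMEPOINT_ALIASES)
    if tp.isna().any():
        bad = df.loc[tp.isna(), "timepoint"].iloc[0]
        raise ValidationError(f"unknown timepoint label {bad!r} in {path}")
    df = df.assign(timepoint=tp)
    df["replicate"] = df["replicate"].astype(int)
    if (df["replicate"] < 1).any():
        raise ValidationError(f"non-positive replicate number in {path}")
    if df["sample"].duplicated().any():
        dup = df.loc[df["sample"].duplicated(), "sample"].iloc[0]
        raise ValidationError(f"duplicate sample {dup!r} in design {path}")
    df = df.set_index("sample")
    key = df[["genotype", "stress", "timepoint", "replicate"]]
    if key.duplicated().any():
        dup = key[key.duplicated()].iloc[0]
        raise ValidationError(
            "duplicate design tuple "
            f"({dup['genotype']}, {dup['stress']}, {dup['timepoint']}, {dup['replicate']})"
        )
    return df


def read_counts(counts_path: str | Path, design_path: str | Path,
                format: str = "tsv") -> CountExperiment:
    """Read counts and design together into a validated :class:`CountExperiment`."""
    genes, samples, counts = read_counts_matrix(counts_path, format=format)
    design = read_design(design_path)
    return CountExperiment(genes=genes, samples=samples, counts=counts, design=design)


def read_gmt(path: str | Path, family: Mapping[str, str] | None = None) -> AnnotationMap:
    """Read a GMT file (term, description, tab-separated gene list).

    Duplicate genes within a line are deduplicated.  An empty file yields an
    empty map with a warning.
    """
    path = Path(path)
    targets: dict[str, frozenset[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: GMT line has <3 fields")
            term = fields[0]
            if term in targets:
                raise FormatError(f"{path}:{lineno}: duplicate term {term!r}")
            genes = frozenset(g for g in fields[2:] if g)
            if not genes:
                raise FormatError(f"{path}:{lineno}: term {term!r} has no genes")
            targets[term] = genes
    if not targets:
        warnings.warn(f"GMT file {path} is empty", stacklevel=2)
        return AnnotationMap(targets={})
    fam = dict(family) if family is not None else None
    if fam is not None:
        fam = {t: fam.get(t, "unassigned") for t in targets}
    return AnnotationMap(targets=targets, family=fam)


def read_family_map(path: str | Path) -> dict[str, str]:
    """Read a two-column headered TSV mapping term → family."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise FormatError(f"family map {path} needs two columns (term, family)")
    return dict(zip(df.iloc[:, 0], df.iloc[:, 1]))


def read_module_map(path: str | Path) -> AnnotationMap:
    """Read a gene → module assignment TSV into a module → genes AnnotationMap."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise FormatError(f"module map {path} needs two columns (gene, module)")
    gene_col, mod_col = df.columns[0], df.columns[1]
    targets = {
        str(mod): frozenset(sub[gene_col])
        for mod, sub in df.groupby(mod_col)
    }
    return AnnotationMap(targets=targets)


def read_gene_lengths(path: str | Path) -> pd.Series:
    """Read a gene → length (bp) TSV."""
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    s = pd.Series(df.iloc[:, 1].to_numpy(float), index=df.iloc[:, 0].astype(str))
    if (s <= 0).any():
        bad = s.index[s <= 0][0]
        raise ValidationError(f"non-positive gene length for {bad!r}")
    return s


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

FLOAT_FMT = "%.6g"  # 6 significant digits for bit-stable diffs


def write_counts(experiment: CountExperiment, counts_path: str | Path,
                 design_path: str | Path | None = None) -> None:
    """Write counts as TSV (genes in rows) and optionally the design TSV."""
    df = pd.DataFrame(experiment.counts, index=experiment.genes,
                      columns=experiment.samples)
    df.index.name = "gene"
    df.to_csv(counts_path, sep="\t")
    if design_path is not None:
        write_design(experiment.design, design_path)


def write_design(design: pd.DataFrame, path: str | Path) -> None:
    out = design.copy()
    out.index.name = "sample"
    out.to_csv(path, sep="\t")


def write_gmt(annotation: AnnotationMap, path: str | Path,
              descriptions: Mapping[str, str] | None = None) -> None:
    with open(path, "w") as fh:
        for term in annotation.terms:
            desc = (descriptions or {}).get(term, "na")
            genes = "\t".join(sorted(annotation.targets[term]))
            fh.write(f"{term}\t{desc}\t{genes}\n")


def write_results(tables: Mapping[str, pd.DataFrame], out_dir: str | Path,
                  seed: int | None = None,
                  config: Mapping | None = None) -> Path:
    """Write one TSV per result table plus a JSON run manifest.

    The manifest records the RNG seed, a hash of the configuration and the
    package version, so a run can be reproduced bit-for-bit.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    from . import __version__

    for name, table in tables.items():
        table.to_csv(out_dir / f"{name}.tsv", sep="\t", index=False,
                     float_format=FLOAT_FMT)
    cfg_json = json.dumps(config, sort_keys=True, default=str) if config else ""
    manifest = {
        "seed": seed,
        "config_hash": hashlib.sha256(cfg_json.encode()).hexdigest(),
        "config": config,
        "version": __version__,
        "tables": sorted(tables),
    }
    manifest_path = out_dir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, default=str))
    return manifest_path
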