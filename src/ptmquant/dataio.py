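"""Canonical feature-level data model, readers, site localization, run cleaning.

The canonical in-memory container is a :class:`pandas.DataFrame` with one row
per quantified spectral feature (peptide ion) per run/channel, on the log2
intensity scale.  All downstream summarization and modeling consumes this
frame.  Columns:

``protein_id``
    protein accession.
``site_id``
    modification site, e.g. ``"S70"``; ``"+"``-joined composite for peptides
    carrying several modified residues; NA for unmodified features.
``peptide``
    (modified) peptide sequence as reported by the spectral-processing tool.
``charge``
    precursor charge state, positive integer.
``feature_id``
    ``peptide/charge``, unique per target.
``run_id``, ``condition``, ``mixture_id``, ``channel``, ``replicate_id``
    experimental design annotation; ``mixture_id``/``channel`` are NA for
    label-free acquisitions.
``log2_intensity``
    log2 feature intensity; NaN when the feature was not observed.
``is_modified``
    whether the feature carries a modification.
``origin``
    ``"enriched"`` (after modification enrichment) or ``"global"``
    (global proteome profiling).
"""

from __future__ import annotations

import re
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO

CANONICAL_COLUMNS = [
    "protein_id",
    "site_id",
    "peptide",
    "charge",
    "feature_id",
    "run_id",
    "condition",
    "mixture_id",
    "channel",
    "replicate_id",
    "log2_intensity",
    "is_modified",
    "origin",
]

#: default in-sequence modification marker: residue followed by "*"
DEFAULT_MARKER = "*"

#: site identifier: residue letter + 1-based position, optionally "+"-joined
#: for peptides carrying several modified residues (e.g. "S70", "S70+T81")
SITE_ID_RE = re.compile(r"^[A-Z]\d+(\+[A-Z]\d+)*$")


class SchemaError(ValueError):
    """A required input column is absent."""


class IntegrityError(ValueError):
    """Duplicate (feature, run, channel) observations."""


class LocalizationError(ValueError):
    """A modified peptide could not be placed in its protein sequence."""


class AmbiguousSiteError(LocalizationError):
    """A peptide maps to more than one position or accession."""


# Column maps: canonical name -> input column, plus whether intensities are
# already log2.  The generic_long dialect is the package's own interchange
# format; the vendor dialects cover the long-format exports of the upstream
# processing tools.
_DIALECTS = {
    "generic_long": {
        "columns": {
            "protein_id": "ProteinName",
            "peptide": "PeptideSequence",
            "charge": "PrecursorCharge",
            "run_id": "Run",
            "condition": "Condition",
            "replicate_id": "BioReplicate",
            "intensity": "Intensity",
        },
        "optional": {"mixture_id": "Mixture", "channel": "Channel", "site_id": "Site"},
        "log2_scale": False,
    },
    "maxquant_sites": {
        "columns": {
            "protein_id": "Proteins",
            "peptide": "Modified sequence",
            "charge": "Charge",
            "run_id": "Raw file",
            "condition": "Condition",
            "replicate_id": "Experiment",
            "intensity": "Intensity",
        },
        "optional": {"mixture_id": "Mixture", "channel": "Channel", "site_id": "Site"},
        "log2_scale": False,
    },
    "spectronaut": {
        "columns": {
            "protein_id": "PG.ProteinAccessions",
            "peptide": "EG.ModifiedSequence",
            "charge": "FG.Charge",
            "run_id": "R.FileName",
            "condition": "R.Condition",
            "replicate_id": "R.Replicate",
            "intensity": "FG.Quantity",
        },
        "optional": {"mixture_id": "Mixture", "channel": "Channel", "site_id": "Site"},
        "log2_scale": False,
    },
}

_MISSING_STRINGS = {"", "na", "nan", "none", "null"}


def _parse_intensity(values: pd.Series, log2_scale: bool) -> pd.Series:
    """Zero / non-positive / NA-encoded intensities become missing."""
    s = values.copy()
    if s.dtype == object:
        s = s.astype(str).str.strip()
        s = s.mask(s.str.lower().isin(_MISSING_STRINGS))
    s = pd.to_numeric(s, errors="coerce")
    s = s.mask(~np.isfinite(s))
    if log2_scale:
        return s.astype(float)
    s = s.mask(s <= 0)
    return np.log2(s.astype(float))


def validate_feature_table(df: pd.DataFrame) -> pd.DataFrame:
    """Check the canonical-table invariants; return the frame unchanged.

    Raises
    ------
    SchemaError
        if a canonical column is missing.
    IntegrityError
        if a (feature_id, run_id, channel) combination occurs twice, or a
        present log2_intensity is non-finite.
    ValueError
        if site annotation disagrees with the is_modified flag.
    """
    for col in CANONICAL_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"missing canonical column: {col!r}")
    key = df[["protein_id", "feature_id", "run_id", "channel"]].astype(str)
    dup = key.duplicated()
    if dup.any():
        first = key[dup].iloc[0].tolist()
        raise IntegrityError(f"duplicate feature observation: {first}")
    present = df["log2_intensity"].notna()
    if present.any() and not np.isfinite(df.loc[present, "log2_intensity"]).all():
        raise IntegrityError("non-finite log2_intensity present")
    # a site on an unmodified record is a contradiction; a modified record
    # without one is merely awaiting localization
    bad = df["site_id"].notna() & ~df["is_modified"]
    if bad.any():
        pep = df.loc[bad, "peptide"].iloc[0]
        raise ValueError(f"unmodified record carries a site_id: peptide {pep!r}")
    sites = df.loc[df["site_id"].notna(), "site_id"].astype(str)
    malformed = ~sites.str.match(SITE_ID_RE)
    if malformed.any():
        raise ValueError(f"malformed site_id {sites[malformed].iloc[0]!r}")
    return df


def read_feature_table(
    path,
    dialect: str = "generic_long",
    origin: str = "enriched",
    marker: str = DEFAULT_MARKER,
    sep: str | None = None,
) -> pd.DataFrame:
    """Read a delimited long-format quantification table into canonical form.

    Parameters
    ----------
    path : str or Path
        CSV/TSV file with one row per feature observation.
    dialect : {"generic_long", "maxquant_sites", "spectronaut"}
        Column naming convention of the input.
    origin : {"enriched", "global"}
        Whether the runs come from modification enrichment or global
        proteome profiling.
    marker : str
        In-sequence modification marker character following the modified
        residue (``"ABS*CK"`` marks the serine).
    sep : str, optional
        Field separator; inferred from the file extension by default.
    """
    if dialect not in _DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}")
    if origin not in ("enriched", "global"):
        raise ValueError(f"unknown origin {origin!r}")
    spec = _DIALECTS[dialect]
    path = Path(path)
    if sep is None:
        sep = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
    raw = pd.read_csv(path, sep=sep)
    for canon, col in spec["columns"].items():
        if col not in raw.columns:
            raise SchemaError(f"dialect {dialect!r} requires column {col!r} ({canon})")

    out = pd.DataFrame(
        {
            "protein_id": raw[spec["columns"]["protein_id"]].astype(str),
            "peptide": raw[spec["columns"]["peptide"]].astype(str),
            "charge": raw[spec["columns"]["charge"]].astype(int),
            "run_id": raw[spec["columns"]["run_id"]].astype(str),
            "condition": raw[spec["columns"]["condition"]].astype(str),
            "replicate_id": raw[spec["columns"]["replicate_id"]].astype(str),
            "log2_intensity": _parse_intensity(
                raw[spec["columns"]["intensity"]], spec["log2_scale"]
            ),
        }
    )
    for canon, col in spec["optional"].items():
        if col in raw.columns:
            vals = raw[col]
            if canon == "site_id":
                vals = vals.mask(vals.astype(str).str.strip().isin(("", "nan", "NA")))
            out[canon] = vals.astype(object).where(vals.notna(), np.nan)
        else:
            out[canon] = np.nan
    for canon in ("site_id", "mixture_id", "channel"):
        out[canon] = out[canon].astype(object)
    out["feature_id"] = out["peptide"] + "/" + out["charge"].astype(str)
    out["is_modified"] = out["peptide"].str.contains(re.escape(marker)) | out[
        "site_id"
    ].notna()
    out["origin"] = origin
    out = out[CANONICAL_COLUMNS]
    return validate_feature_table(out)


def write_feature_table(df: pd.DataFrame, path, sep: str = ",") -> None:
    """Write a canonical table back to generic_long delimited text.

    Intensities are written on the raw (linear) scale so that
    :func:`read_feature_table` round-trips losslessly.
    """
    out = pd.DataFrame(
        {
            "ProteinName": df["protein_id"],
            "PeptideSequence": df["peptide"],
            "PrecursorCharge": df["charge"],
            "Run": df["run_id"],
            "Condition": df["condition"],
            "BioReplicate": df["replicate_id"],
            "Intensity": np.exp2(df["log2_intensity"]),
            "Mixture": df["mixture_id"],
            "Channel": df["channel"],
            "Site": df["site_id"],
        }
    )
    out.to_csv(path, sep=sep, index=False)


def _strip_marker(peptide: str, marker: str) -> tuple[str, list[int]]:
    """Return the plain sequence and 0-based positions of marked residues."""
    plain = []
    marked = []
    for ch in peptide:
        if ch == marker:
            if not plain:
                raise LocalizationError(f"marker at start of peptide {peptide!r}")
            marked.append(len(plain) - 1)
        else:
            plain.append(ch)
    return "".join(plain), marked


def read_fasta(path) -> dict[str, str]:
    """Parse a FASTA database into accession -> sequence.

    UniProt-style ``db|ACC|NAME`` headers are keyed by the accession token;
    plain headers by the whole first word.
    """
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        header = rec.id
        acc = header.split("|")[1] if header.count("|") >= 2 else header
        seqs[acc] = str(rec.seq).upper()
    return seqs


def locate_sites(
    table: pd.DataFrame,
    fasta,
    mod_residues: set[str] | None = None,
    marker: str = DEFAULT_MARKER,
    keep_first: bool = False,
) -> pd.DataFrame:
    """Assign protein-level site identifiers to modified peptides.

    For each modified peptide the plain sequence is located in the full
    protein sequence from the FASTA database; each marked residue becomes a
    token ``<residue letter><1-based protein position>`` (``"S70"``), and
    peptides with several marked residues get a ``"+"``-joined composite.

    Parameters
    ----------
    table : canonical feature table.
    fasta : path to a FASTA file, or a prebuilt accession->sequence mapping.
    mod_residues : optional set of residue letters allowed to carry the
        modification; a marked residue outside the set raises.
    keep_first : if the peptide occurs at several positions in the protein,
        keep the first occurrence instead of raising
        :class:`AmbiguousSiteError`.

    Idempotent: records that already carry a ``site_id`` are left untouched.
    """
    seqs = fasta if isinstance(fasta, dict) else read_fasta(fasta)
    out = table.copy()
    out["site_id"] = out["site_id"].astype(object)
    todo = out["is_modified"] & out["site_id"].isna()
    cache: dict[tuple[str, str], str] = {}
    for idx in out.index[todo]:
        protein = out.at[idx, "protein_id"]
        peptide = out.at[idx, "peptide"]
        key = (protein, peptide)
        if key not in cache:
            if protein not in seqs:
                raise LocalizationError(f"accession {protein!r} absent from FASTA")
            plain, marked = _strip_marker(peptide, marker)
            if not marked:
                raise LocalizationError(
                    f"modified peptide {peptide!r} carries no {marker!r} marker"
                )
            seq = seqs[protein]
            start = seq.find(plain)
            if start < 0:
                raise LocalizationError(
                    f"peptide {peptide!r} not found in protein {protein!r}"
                )
            if not keep_first and seq.find(plain, start + 1) >= 0:
                raise AmbiguousSiteError(
                    f"peptide {peptide!r} occurs more than once in {protein!r}"
                )
            tokens = []
            for pos in marked:
                residue = plain[pos]
                if mod_residues is not None and residue not in mod_residues:
                    raise LocalizationError(
                        f"residue {residue!r} in {peptide!r} not in mod_residues"
                    )
                tokens.append(f"{residue}{start + pos + 1}")
            cache[key] = "+".join(tokens)
        out.at[idx, "site_id"] = cache[key]
    return out


def clean_enriched(table: pd.DataFrame) -> pd.DataFrame:
    """Drop unmodified features from modification-enriched runs.

    Enrichment runs are analyzed at the site level only; any co-identified
    unmodified features are discarded before summarization.
    """
    if len(table) == 0:
        return table.copy()
    if not (table["origin"] == "enriched").all():
        raise ValueError("clean_enriched expects origin='enriched' records")
    return table[table["is_modified"]].reset_index(drop=True)
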