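"""Weighted gene-expression signatures and PD-L1 expression analysis.

A signature is a list of (gene, weight) pairs.  Its score on a single
expression profile is the weight-normalized mean of the log-expression of
the positively weighted genes minus the weight-normalized mean of the
negatively weighted genes::

    score = sum_{w_i>0} w_i E_i / sum_{w_i>0} w_i
          - sum_{w_i<0} |w_i| E_i / sum_{w_i<0} |w_i|

with E_i in units of log10(TPM + 1).  Each term is a convex combination of
expression values, so the score is invariant to adding a constant to every
E_i whenever both sign groups are non-empty.  Note the normalization of the
negative group uses |w_i|; dividing by the (negative) raw weight sum would
flip the sign of the subtracted term, which is plainly not the intent of
"positive-gene mean minus negative-gene mean".

Microarray intensities are made comparable to RNA-seq TPM by per-gene
quantile matching ("pseudo-TPM"): in log space, an affine map per gene
sends the observed (0%, 90%) quantiles onto reference quantiles taken from
an RNA-seq compendium.
"""

from __future__ import annotations

import gzip
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse
from scipy import stats as spstats

__all__ = [
    "GeneSignature",
    "ExpressionMatrix",
    "QuantileReference",
    "CorrelationResult",
    "PDL1_GENE",
    "pseudo_tpm_normalize",
    "expression_score",
    "metabolic_activity_score",
    "pdl1_positive_fraction",
    "correlate_pdl1_with_signature",
]

#: Default gene symbol used for PD-L1 (programmed death-ligand 1).
PDL1_GENE = "CD274"

SignatureRole = Literal[
    "primary_metabolism", "secondary_metabolism", "angiogenesis", "custom"
]
ExpressionUnit = Literal["TPM", "log10_tpm_plus1", "raw_intensity"]

_VALID_ROLES = {"primary_metabolism", "secondary_metabolism", "angiogenesis", "custom"}
_VALID_UNITS = {"TPM", "log10_tpm_plus1", "raw_intensity"}


@dataclass(frozen=True)
class GeneSignature:
    """A named, weighted gene set.

    Parameters
    ----------
    entries
        Sequence of ``(gene_id, weight)`` pairs.  Gene ids must be unique
        and at least one weight must be nonzero.
    name
        Human-readable signature name.
    role
        One of ``primary_metabolism``, ``secondary_metabolism``,
        ``angiogenesis`` or ``custom``.
    """

    entries: tuple[tuple[str, float], ...]
    name: str = "signature"
    role: SignatureRole = "custom"

    def __init__(
        self,
        entries: Sequence[tuple[str, float]],
        name: str = "signature",
        role: SignatureRole = "custom",
    ) -> None:
        entries = tuple((str(g), float(w)) for g, w in entries)
        genes = [g for g, _ in entries]
        if len(set(genes)) != len(genes):
            dupes = sorted({g for g in genes if genes.count(g) > 1})
            raise ValueError(f"duplicate gene ids in signature: {dupes}")
        if not any(w != 0.0 for _, w in entries):
            raise ValueError("signature needs at least one nonzero weight")
        if not all(np.isfinite(w) for _, w in entries):
            raise ValueError("signature weights must be finite")
        if role not in _VALID_ROLES:
            raise ValueError(f"unknown role {role!r}")
        object.__setattr__(self, "entries", entries)
        object.__setattr__(self, "name", str(name))
        object.__setattr__(self, "role", role)

    @property
    def genes(self) -> list[str]:
        return [g for g, _ in self.entries]

    @property
    def weights(self) -> np.ndarray:
        return np.array([w for _, w in self.entries], dtype=float)

    @classmethod
    def from_tsv(cls, path: str | Path, name: str | None = None) -> "GeneSignature":
        """Read a two-column (gene_id, weight) TSV with an optional
        ``#role: <role>`` header line."""
        path = Path(path)
        role: SignatureRole = "custom"
        entries: list[tuple[str, float]] = []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line:
                    continue
                if line.startswith("#"):
                    key, _, val = line[1:].partition(":")
                    if key.strip() == "role":
                        role = val.strip()  # validated by __init__
                    continue
                gene, _, w = line.partition("\t")
                entries.append((gene, float(w)))
        return cls(entries, name=name or path.stem, role=role)

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(f"#role: {self.role}\n")
            for gene, w in self.entries:
                fh.write(f"{gene}\t{w:g}\n")


@dataclass
class ExpressionMatrix:
    """Genes x observations expression values with an explicit unit.

    The unit is carried so conversions are always explicit; scoring
    functions check it and refuse silently mixed conventions.
    """

    values: pd.DataFrame  # index: gene ids, columns: observation ids
    unit: ExpressionUnit = "TPM"

    def __post_init__(self) -> None:
        if not isinstance(self.values, pd.DataFrame):
            self.values = pd.DataFrame(self.values)
        if self.unit not in _VALID_UNITS:
            raise ValueError(f"unknown expression unit {self.unit!r}")
        if self.values.index.has_duplicates:
            raise ValueError("duplicate gene ids in expression matrix")
        if self.unit == "TPM" and (self.values.to_numpy() < 0).any():
            raise ValueError("TPM values must be non-negative")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def obs_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_obs(self) -> int:
        return self.values.shape[1]

    def to_log10_tpm(self) -> "ExpressionMatrix":
        """Return a log10(TPM + 1) view of a TPM matrix (identity if
        already in log units)."""
        if self.unit == "log10_tpm_plus1":
            return self
        if self.unit != "TPM":
            raise ValueError(
                f"cannot log-transform unit {self.unit!r}; "
                "normalize raw intensities first"
            )
        return ExpressionMatrix(np.log10(self.values + 1.0), unit="log10_tpm_plus1")

    # ---- I/O ----------------------------------------------------------

    def to_tsv(self, path: str | Path) -> None:
        """Write as (gzip-)TSV, genes as rows, one header row of cell ids."""
        path = Path(path)
        opener = gzip.open if path.suffix == ".gz" else open
        with opener(path, "wt") as fh:
            self.values.to_csv(fh, sep="\t", index_label="gene_id")

    @classmethod
    def from_tsv(cls, path: str | Path, unit: ExpressionUnit = "TPM") -> "ExpressionMatrix":
        path = Path(path)
        compression = "gzip" if path.suffix == ".gz" else None
        df = pd.read_csv(path, sep="\t", index_col=0, compression=compression)
        df.index.name = None
        return cls(df, unit=unit)

    def to_mtx(self, prefix: str | Path) -> None:
        """Write MatrixMarket triplets plus ``<prefix>.genes.txt`` /
        ``<prefix>.obs.txt`` sidecars."""
        prefix = Path(prefix)
        spio.mmwrite(str(prefix) + ".mtx", sparse.csr_matrix(self.values.to_numpy()))
        Path(str(prefix) + ".genes.txt").write_text("\n".join(self.gene_ids) + "\n")
        Path(str(prefix) + ".obs.txt").write_text("\n".join(self.obs_ids) + "\n")

    @classmethod
    def from_mtx(cls, prefix: str | Path, unit: ExpressionUnit = "TPM") -> "ExpressionMatrix":
        prefix = Path(prefix)
        m = spio.mmread(str(prefix) + ".mtx").toarray()
        genes = Path(str(prefix) + ".genes.txt").read_text().splitlines()
        obs = Path(str(prefix) + ".obs.txt").read_text().splitlines()
        return cls(pd.DataFrame(m, index=genes, columns=obs), unit=unit)


@dataclass(frozen=True)
class QuantileReference:
    """Per-gene (0%, 90%) reference quantiles in log10(TPM + 1) space."""

    q0: pd.Series
    q90: pd.Series

    def __post_init__(self) -> None:
        if not self.q0.index.equals(self.q90.index):
            raise ValueError("q0 and q90 must share a gene index")
        if (self.q90 < self.q0).any():
            bad = list(self.q90.index[self.q90 < self.q0])
            raise ValueError(f"q90 < q0 for genes: {bad}")

    @classmethod
    def from_matrix(cls, matrix: ExpressionMatrix) -> "QuantileReference":
        """Build a reference from an RNA-seq compendium matrix (TPM or log)."""
        logm = matrix.to_log10_tpm().values
        return cls(q0=logm.min(axis=1), q90=logm.quantile(0.9, axis=1))

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame({"q0": self.q0, "q90": self.q90}).to_csv(
            path, sep="\t", index_label="gene_id"
        )

    @classmethod
    def from_tsv(cls, path: str | Path) -> "QuantileReference":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(q0=df["q0"], q90=df["q90"])


@dataclass(frozen=True)
class CorrelationResult:
    """Pearson correlation with its two-sided p-value."""

    r: float
    p: float
    n: int

    def __post_init__(self) -> None:
        if not -1.0 <= self.r <= 1.0:
            raise ValueError("r outside [-1, 1]")
        if not 0.0 <= self.p <= 1.0:
            raise ValueError("p outside [0, 1]")
        if self.n < 3:
            raise ValueError("need n >= 3 observations")


def pseudo_tpm_normalize(
    matrix: ExpressionMatrix, ref: QuantileReference
) -> ExpressionMatrix:
    """Quantile-match raw intensities to a TPM reference, gene by gene.

    For each gene the observed values are log-transformed (log10(x + 1) for
    raw intensities; values already in log10(TPM + 1) are taken as-is) and
    affinely mapped so the observed minimum (0% quantile) and 90% quantile
    land on the reference (q0, q90).  The map is affine and increasing, so
    rank order within each gene is preserved; applying it twice against the
    same reference is the identity.

    A gene with zero spread (observed q90 == q0) carries no usable scale
    and is mapped to the constant reference q0, with a warning.
    """
    if matrix.unit == "raw_intensity":
        if (matrix.values.to_numpy() < 0).any():
            raise ValueError("raw intensities must be non-negative")
        logv = np.log10(matrix.values + 1.0)
    elif matrix.unit == "log10_tpm_plus1":
        logv = matrix.values
    else:
        raise ValueError(
            "pseudo-TPM normalization expects raw_intensity (or already "
            f"log-transformed) input, got unit {matrix.unit!r}"
        )

    missing = set(matrix.gene_ids) - set(ref.q0.index)
    if missing:
        raise KeyError(f"genes absent from quantile reference: {sorted(missing)}")

    obs_q0 = logv.min(axis=1)
    obs_q90 = logv.quantile(0.9, axis=1)
    ref_q0 = ref.q0.loc[logv.index]
    ref_q90 = ref.q90.loc[logv.index]

    spread = obs_q90 - obs_q0
    flat = spread <= 0
    if flat.any():
        warnings.warn(
            f"{int(flat.sum())} gene(s) with zero spread mapped to the "
            "constant reference q0",
            stacklevel=2,
        )
    scale = (ref_q90 - ref_q0).where(~flat, 0.0) / spread.where(~flat, 1.0)
    out = (logv.sub(obs_q0, axis=0)).mul(scale, axis=0).add(ref_q0, axis=0)
    return ExpressionMatrix(out, unit="log10_tpm_plus1")


def expression_score(
    sig: GeneSignature,
    profile: Mapping[str, float] | pd.Series,
    missing: Literal["error", "drop"] = "error",
) -> float:
    """Score one log-expression profile against a signature.

    ``profile`` maps gene id to expression in log10(TPM + 1).  If a
    signature gene is absent, the default policy is to raise; with
    ``missing="drop"`` absent genes are dropped and the remaining weights
    renormalize automatically (each sign-group term is a weighted mean).
    An empty sign group contributes 0.
    """
    profile = pd.Series(profile, dtype=float)
    present = [(g, w) for g, w in sig.entries if g in profile.index]
    if len(present) < len(sig.entries):
        absent = [g for g, _ in sig.entries if g not in profile.index]
        if missing == "error":
            raise KeyError(
                f"signature {sig.name!r} genes absent from profile: {absent}"
            )
        if not present:
            raise KeyError(f"no gene of signature {sig.name!r} present in profile")

    score = 0.0
    for sign in (1, -1):
        grp = [(g, abs(w)) for g, w in present if np.sign(w) == sign]
        if not grp:
            continue
        genes = [g for g, _ in grp]
        w = np.array([wt for _, wt in grp])
        score += sign * float(np.average(profile[genes].to_numpy(), weights=w))
    return score


def _score_matrix(
    sig: GeneSignature, logm: pd.DataFrame, missing: Literal["error", "drop"]
) -> np.ndarray:
    """Vectorized per-column signature scores on a log-expression matrix."""
    present = [(g, w) for g, w in sig.entries if g in logm.index]
    if len(present) < len(sig.entries) and missing == "error":
        absent = [g for g, _ in sig.entries if g not in logm.index]
        raise KeyError(f"signature {sig.name!r} genes absent from matrix: {absent}")
    if not present:
        raise KeyError(f"no gene of signature {sig.name!r} present in matrix")
    scores = np.zeros(logm.shape[1])
    for sign in (1, -1):
        grp = [(g, abs(w)) for g, w in present if np.sign(w) == sign]
        if not grp:
            continue
        sub = logm.loc[[g for g, _ in grp]].to_numpy()
        w = np.array([wt for _, wt in grp])
        scores += sign * (w @ sub) / w.sum()
    return scores


def metabolic_activity_score(
    primary: GeneSignature,
    secondary: GeneSignature,
    profile: Mapping[str, float] | pd.Series,
    missing: Literal["error", "drop"] = "error",
) -> float:
    """Total metabolic-activity score: primary plus secondary sub-score."""
    return expression_score(primary, profile, missing) + expression_score(
        secondary, profile, missing
    )


def pdl1_positive_fraction(
    matrix: ExpressionMatrix, pdl1_gene: str = PDL1_GENE
) -> float:
    """Fraction of observations with PD-L1 TPM strictly greater than 1.

    TPM > 1 is the detectability cutoff for calling a cell PD-L1 positive;
    a cell at exactly TPM = 1 is not counted.
    """
    if matrix.unit != "TPM":
        raise ValueError(f"positivity calling needs TPM units, got {matrix.unit!r}")
    if pdl1_gene not in matrix.values.index:
        raise KeyError(f"PD-L1 gene {pdl1_gene!r} absent from matrix")
    tpm = matrix.values.loc[pdl1_gene].to_numpy()
    return float(np.mean(tpm > 1.0))


def correlate_pdl1_with_signature(
    matrix: ExpressionMatrix,
    sig: GeneSignature,
    pdl1_gene: str = PDL1_GENE,
    log_transform: bool = True,
    missing: Literal["error", "drop"] = "error",
) -> CorrelationResult:
    """Pearson correlation of per-cell PD-L1 expression with per-cell
    signature scores.

    Scores are always computed on log10(TPM + 1) values.  ``log_transform``
    controls only the PD-L1 axis: by default PD-L1 is correlated in log
    space as well; set it False to correlate against raw TPM.
    """
    if pdl1_gene not in matrix.values.index:
        raise KeyError(f"PD-L1 gene {pdl1_gene!r} absent from matrix")
    if matrix.n_obs < 3:
        raise ValueError("need at least 3 observations for a correlation")
    logm = matrix.to_log10_tpm().values
    scores = _score_matrix(sig, logm, missing)
    if log_transform:
        pdl1 = logm.loc[pdl1_gene].to_numpy()
    else:
        if matrix.unit != "TPM":
            raise ValueError("raw-TPM correlation requires a TPM matrix")
        pdl1 = matrix.values.loc[pdl1_gene].to_numpy()
    if np.ptp(pdl1) == 0 or np.ptp(scores) == 0:
        raise ValueError("correlation undefined: a variable has zero variance")
    res = spstats.pearsonr(pdl1, scores)
    return CorrelationResult(r=float(res.statistic), p=float(res.pvalue), n=len(pdl1))
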