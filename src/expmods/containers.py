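"""In-memory containers for the expression side of the pipeline.

Two matrix containers are used: :class:`ProbeMatrix` holds probe-level
intensities (raw or normalized scale) together with optional per-probe,
per-sample detection p-values and a probe->gene annotation map;
:class:`ExpressionMatrix` holds gene-level log2 expression with case/control
sample labels.  Both wrap a pandas DataFrame (rows = features, columns =
samples) and round-trip through plain tab-separated text.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

CASE = "case"
CONTROL = "control"


def _check_unique(index: pd.Index, what: str) -> None:
    if index.has_duplicates:
        dup = index[index.duplicated()].unique()[:5].tolist()
        raise ValueError(f"duplicate {what}: {dup}")


@dataclass
class ExpressionMatrix:
    """Gene-level log2 expression with sample group labels.

    Parameters
    ----------
    values : DataFrame
        genes x samples, log2 scale.
    groups : Series
        sample id -> ``"case"`` or ``"control"``; index must cover the
        sample columns of ``values``.
    """

    values: pd.DataFrame
    groups: pd.Series

    def __post_init__(self) -> None:
        _check_unique(self.values.index, "gene ids")
        _check_unique(self.values.columns, "sample ids")
        self.groups = pd.Series(self.groups)
        missing = self.values.columns.difference(self.groups.index)
        if len(missing):
            raise ValueError(f"samples without a group label: {list(missing)[:5]}")
        bad = set(self.groups.loc[self.values.columns]) - {CASE, CONTROL}
        if bad:
            raise ValueError(f"group labels must be 'case'/'control', got {bad}")

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns

    def case_samples(self) -> list[str]:
        g = self.groups.loc[self.values.columns]
        return list(g.index[g == CASE])

    def control_samples(self) -> list[str]:
        g = self.groups.loc[self.values.columns]
        return list(g.index[g == CONTROL])

    # -- plain-text round trip -------------------------------------------------
    def write(self, matrix_path: str | Path, groups_path: str | Path) -> None:
        self.values.to_csv(matrix_path, sep="\t", index_label="gene_id")
        self.groups.loc[self.values.columns].rename("group").to_csv(
            groups_path, sep="\t", index_label="sample_id"
        )

    @classmethod
    def read(cls, matrix_path: str | Path, groups_path: str | Path) -> "ExpressionMatrix":
        values = pd.read_csv(matrix_path, sep="\t", index_col=0)
        groups = pd.read_csv(groups_path, sep="\t", index_col=0)["group"]
        return cls(values=values, groups=groups)


@dataclass
class ProbeMatrix:
    """Probe-level intensity matrix with optional detection p-values.

    ``detection_p`` (when present) must be aligned with ``values`` in both
    dimensions.  ``probe2gene`` maps probe id -> gene id; probes without an
    entry are treated as unannotated.  ``groups`` carries the sample labels
    through preprocessing so that collapsing to genes can emit an
    :class:`ExpressionMatrix` directly.
    """

    values: pd.DataFrame
    detection_p: pd.DataFrame | None = None
    probe2gene: pd.Series | None = None
    groups: pd.Series | None = field(default=None)

    def __post_init__(self) -> None:
        _check_unique(self.values.index, "probe ids")
        _check_unique(self.values.columns, "sample ids")
        if self.detection_p is not None:
            if self.detection_p.shape != self.values.shape:
                raise ValueError(
                    "detection_p shape "
                    f"{self.detection_p.shape} != values shape {self.values.shape}"
                )
            # align to the value matrix so positional masks agree
            self.detection_p = self.detection_p.loc[self.values.index, self.values.columns]
        if self.probe2gene is not None:
            self.probe2gene = pd.Series(self.probe2gene)

    @property
    def n_probes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def replace_values(self, new: pd.DataFrame | np.ndarray) -> "ProbeMatrix":
        """Same metadata, new value matrix (used by the normalization steps)."""
        values = pd.DataFrame(
            np.asarray(new), index=self.values.index, columns=self.values.columns
        )
        det = None
        if self.detection_p is not None:
            det = self.detection_p.copy()
        return ProbeMatrix(
            values=values,
            detection_p=det,
            probe2gene=None if self.probe2gene is None else self.probe2gene.copy(),
            groups=None if self.groups is None else self.groups.copy(),
        )

    def write(self, matrix_path: str | Path, detection_path: str | Path | None = None,
              annotation_path: str | Path | None = None) -> None:
        self.values.to_csv(matrix_path, sep="\t", index_label="probe_id")
        if detection_path is not None and self.detection_p is not None:
            self.detection_p.to_csv(detection_path, sep="\t", index_label="probe_id")
        if annotation_path is not None and self.probe2gene is not None:
            self.probe2gene.rename("gene_id").to_csv(
                annotation_path, sep="\t", index_label="probe_id"
            )

    @classmethod
    def read(cls, matrix_path: str | Path, detection_path: str | Path | None = None,
             annotation_path: str | Path | None = None,
             groups_path: str | Path | None = None) -> "ProbeMatrix":
        values = pd.read_csv(matrix_path, sep="\t", index_col=0)
        detection = None
        if detection_path is not None:
            detection = pd.read_csv(detection_path, sep="\t", index_col=0)
        probe2gene = None
        if annotation_path is not None:
            ann = pd.read_csv(annotation_path, sep="\t", index_col=0, dtype=str)
            probe2gene = ann.iloc[:, 0]
        groups = None
        if groups_path is not None:
            groups = pd.read_csv(groups_path, sep="\t", index_col=0)["group"]
        return cls(values=values, detection_p=detection, probe2gene=probe2gene,
                   groups=groups)
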