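"""End-to-end study orchestration: align → fields → PLS → validate → contour.

`run_study` is the library-level composite the command-line ``run``
subcommand wraps; it returns every intermediate artifact so callers can
inspect or persist them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .align import CoreAligner
from .chem import DataSet, assign_atom_parameters, assign_gasteiger_charges
from .contours import ContourMap, contour_levels, stdev_coeff_field
from .fields import FieldConfig, FieldGenerator, FieldMatrix
from .pls import PLSQsar
from .validation import ValidationReport, external_validate

__all__ = ["StudyResult", "prepare_molecules", "run_study"]


@dataclass
class StudyResult:
    """Artifacts of one full 3D-QSAR study."""

    aligned: DataSet
    generator: FieldGenerator
    matrix: FieldMatrix
    model: PLSQsar
    validation: ValidationReport | None
    contour_maps: dict[str, ContourMap]

    def statistics_frame(self) -> pd.DataFrame:
        """One-row model summary mirroring the usual PLS statistics table
        (ONC, q², r², SEE, F, per-field contribution percentages)."""
        m = self.model
        row = {"ONC": m.n_components_, "q2": m.q2_, "r2": m.r2_, "SEE": m.see_, "F": m.f_}
        if m.contributions_:
            for f, pct in m.contributions_.items():
                row[f"contrib_{f}"] = pct
        if self.validation is not None:
            row["r2_pred"] = self.validation.r2_pred
        return pd.DataFrame([row])


def prepare_molecules(data: DataSet, assign_charges: bool = True) -> DataSet:
    """Assign Gasteiger charges and per-atom field parameters to a set."""
    mols = []
    for m in data:
        m2 = assign_gasteiger_charges(m) if assign_charges else m.copy()
        mols.append(assign_atom_parameters(m2))
    return DataSet(mols, dict(data.split))


def run_study(data: DataSet, core_smarts: str, template_id: str,
              method: str = "CoMFA", fields: tuple[str, ...] | None = None,
              config: FieldConfig | None = None, spacing: float = 2.0,
              margin: float = 4.0, max_components: int = 10,
              n_components: int | None = None,
              assign_charges: bool = True) -> StudyResult:
    """Run the full modeling workflow on a split data set.

    The field lattice, column mask and block scales are learned on the
    training molecules only; test molecules are projected onto those
    columns for external validation.  When the set carries no test split,
    validation is skipped.
    """
    if config is None:
        config = FieldConfig() if method == "CoMFA" else FieldConfig(min_sigma=0.0)
    prepared = prepare_molecules(data, assign_charges=assign_charges)
    aligner = CoreAligner(core_smarts=core_smarts, template_id=template_id).fit(prepared)
    aligned = aligner.transform(prepared)

    has_split = bool(aligned.split) and any(v == "test" for v in aligned.split.values())
    train = aligned.subset("train") if has_split else aligned
    gen = FieldGenerator(method=method, fields=fields, config=config,
                         spacing=spacing, margin=margin)
    gen.fit(train)
    X_train = gen.matrix_
    y_train = train.activities()
    if np.isnan(y_train).any():
        raise ValueError("training molecules must all carry an activity")
    model = PLSQsar(n_components=n_components, max_components=max_components)
    model.fit(X_train, y_train)

    report = None
    if has_split:
        test = aligned.subset("test")
        X_test = gen.transform(test)
        report = external_validate(model, X_test, test.activities(), ids=test.ids())

    maps = {}
    for f in X_train.fields:
        cmap = stdev_coeff_field(model, X_train, f)
        if np.any(cmap.values != 0):
            contour_levels(cmap)
        maps[f] = cmap
    return StudyResult(aligned=aligned, generator=gen, matrix=X_train,
                       model=model, validation=report, contour_maps=maps)
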