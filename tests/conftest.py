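import numpy as np
import pytest

from anrisk.data import (
    ACAN_TP1,
    HC,
    FeatureDescriptor,
    FeatureKind,
    FeatureTable,
    SubjectRecord,
)

KINDS_CYCLE = (
    FeatureKind.CORTICAL_THICKNESS,
    FeatureKind.SUBCORTICAL_GM_VOLUME,
    FeatureKind.CSF_VOLUME,
)


def build_table(
    values,
    groups,
    ages=None,
    etiv=None,
    bmi=None,
    outcome=None,
    kinds=None,
    subject_ids=None,
):
    """Assemble a FeatureTable from raw pieces, with sensible metadata defaults."""
    values = np.asarray(values, dtype=float)
    n, p = values.shape
    ages = np.full(n, 20.0) if ages is None else np.asarray(ages, dtype=float)
    etiv = np.full(n, 1.5e6) if etiv is None else np.asarray(etiv, dtype=float)
    bmi = np.zeros(n) if bmi is None else np.asarray(bmi, dtype=float)
    kinds = kinds or [KINDS_CYCLE[j % 3] for j in range(p)]
    records = [
        SubjectRecord(
            scan_id=f"s{i:03d}",
            subject_id=subject_ids[i] if subject_ids else f"subj{i:03d}",
            group=groups[i],
            age=float(ages[i]),
            etiv=float(etiv[i]),
            bmi_sds=float(bmi[i]),
            outcome=None if outcome is None else float(outcome[i]),
        )
        for i in range(n)
    ]
    descriptors = [
        FeatureDescriptor(
            name=(
                f"lh_feat{j:03d}_thickness"
                if kinds[j] == FeatureKind.CORTICAL_THICKNESS
                else f"feat{j:03d}"
            ),
            kind=kinds[j],
            hemisphere="left" if kinds[j] == FeatureKind.CORTICAL_THICKNESS else "none",
            region_label=f"region{j:03d}",
        )
        for j in range(p)
    ]
    return FeatureTable(records=records, descriptors=descriptors, values=values)


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def two_group_table(rng):
    """60 HC + 60 patients, 12 features, pure noise plus a planted shift."""
    n, p = 120, 12
    values = rng.standard_normal((n, p))
    groups = [HC] * 60 + [ACAN_TP1] * 60
    values[60:, :4] += 1.0
    ages = rng.uniform(12, 30, n)
    etiv = rng.normal(1.5e6, 1.5e5, n)
    return build_table(values, groups, ages=ages, etiv=etiv)
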