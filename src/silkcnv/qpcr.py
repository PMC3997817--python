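"""Comparative-Ct (2^-ddCt) copy-number quantification and its F-test check.

The comparative-Ct method quantifies a target region against a control
amplicon of known copy number: dCt = Ct_target - Ct_control per sample,
ddCt = dCt_sample - dCt_reference against a designated reference individual,
and RQ = 2^-ddCt is the fold copy-number difference relative to the
reference (perfect amplification efficiency assumed). Estimated copies =
RQ * reference copies. An F-test on replicate copy-number estimates asks
whether a tested individual's variance exceeds the reference's — unequal
variance is the signature of a real copy-number difference among
individuals.

Replicate Ct values are averaged on the Ct scale before differencing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import f as f_dist

__all__ = [
    "CtTable",
    "delta_ct",
    "relative_quantity",
    "copy_number_estimate",
    "variance_f_test",
    "analyze_ct_table",
    "simulate_ct_table",
]

CT_COLUMNS = ["sample_id", "target_id", "control_id", "replicate", "ct"]


@dataclass
class CtTable:
    """Replicate Ct values per (sample, target, control) plus the design.

    ``control_copies`` is the copy number of the control amplicon in the
    genome (1 for a single-copy control, 2 for a two-copy control region);
    ``reference_copies`` is the assumed copy number of each target in the
    reference individual.
    """

    data: pd.DataFrame
    reference_sample_id: str
    control_copies: int = 1
    reference_copies: int = 2

    def __post_init__(self) -> None:
        missing = set(CT_COLUMNS) - set(self.data.columns)
        if missing:
            raise ValueError(f"Ct table missing columns: {sorted(missing)}")
        if (self.data["ct"] <= 0).any():
            raise ValueError("Ct values must be positive")
        if self.reference_sample_id not in set(self.data["sample_id"]):
            raise ValueError(
                f"reference sample {self.reference_sample_id!r} not in table"
            )

    @classmethod
    def from_tsv(cls, path, reference_sample_id, **kw) -> "CtTable":
        return cls(pd.read_csv(path, sep="\t"), reference_sample_id, **kw)


def delta_ct(ct_target_mean: float, ct_control_mean: float) -> float:
    """dCt = mean target Ct minus mean control Ct."""
    return float(ct_target_mean) - float(ct_control_mean)


def relative_quantity(delta_ct_sample: float, delta_ct_reference: float) -> float:
    """RQ = 2^-(dCt_sample - dCt_reference); equals 1 when ddCt = 0."""
    return float(2.0 ** -(delta_ct_sample - delta_ct_reference))


def copy_number_estimate(
    rq: float, reference_copies: float = 2, control_copies: float | None = None
) -> float:
    """Estimated copies = RQ * reference copies.

    The control's own copy number cancels in ddCt when every sample uses the
    same control; ``control_copies`` is accepted for mixed-control designs
    where the caller has already put RQ on a per-control scale.
    """
    if rq <= 0:
        raise ValueError("RQ must be > 0")
    return float(rq) * float(reference_copies)


def variance_f_test(
    estimates_test: np.ndarray, estimates_reference: np.ndarray
) -> tuple[float, float, float]:
    """(F, two-sided p, one-sided p) for variance homogeneity.

    F = s2_test / s2_reference with (n_test-1, n_ref-1) df. The one-sided p
    tests "greater variance in the tested sample". Zero reference variance
    with non-zero test variance is reported as p = 0 with a warning.
    """
    a = np.asarray(estimates_test, dtype=float)
    b = np.asarray(estimates_reference, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need >= 2 replicates per sample")
    s2a, s2b = a.var(ddof=1), b.var(ddof=1)
    if s2b == 0:
        if s2a == 0:
            return 1.0, 1.0, 1.0
        import warnings

        warnings.warn("zero reference variance; p reported as 0", stacklevel=2)
        return np.inf, 0.0, 0.0
    F = s2a / s2b
    dfn, dfd = a.size - 1, b.size - 1
    one_sided = float(f_dist.sf(F, dfn, dfd))
    two_sided = float(2 * min(f_dist.sf(F, dfn, dfd), f_dist.cdf(F, dfn, dfd)))
    return float(F), min(two_sided, 1.0), one_sided


def analyze_ct_table(table: CtTable) -> pd.DataFrame:
    """Per (sample, target): dCt, ddCt, RQ, estimated copies, F-test vs ref.

    Replicates are averaged on the Ct scale. The F-test compares per-replicate
    copy-number estimates (paired by replicate index) between each sample and
    the reference sample.
    """
    df = table.data
    ref = table.reference_sample_id

    def rep_estimates(sub: pd.DataFrame, dct_ref: float) -> np.ndarray:
        # per-replicate dCt -> per-replicate copy estimate
        piv = sub.pivot_table(
            index="replicate", columns="kind", values="ct", aggfunc="mean"
        )
        dct = piv["target"] - piv["control"]
        return (2.0 ** -(dct - dct_ref) * table.reference_copies).to_numpy()

    rows = []
    for target, tsub in df.groupby("target_id", sort=True):
        if (tsub["control_id"] == target).all():
            continue  # the control amplicon itself is not a target
        tagged = []
        for sid, ssub in tsub.groupby("sample_id", sort=True):
            control_id = ssub["control_id"].iloc[0]
            ctrl = df[
                (df["sample_id"] == sid) & (df["target_id"] == control_id)
            ]
            if ctrl.empty:
                # control rows live in the same table under their own target id
                raise ValueError(
                    f"no control Ct rows ({control_id}) for sample {sid}"
                )
            merged = pd.concat(
                [ssub.assign(kind="target"), ctrl.assign(kind="control")]
            )
            dct = delta_ct(ssub["ct"].mean(), ctrl["ct"].mean())
            tagged.append((sid, dct, merged))
        ref_entry = next((t for t in tagged if t[0] == ref), None)
        if ref_entry is None:
            raise ValueError(f"reference sample missing for target {target}")
        dct_ref = ref_entry[1]
        ref_reps = rep_estimates(ref_entry[2], dct_ref)
        for sid, dct, merged in tagged:
            rq = relative_quantity(dct, dct_ref)
            cn = copy_number_estimate(rq, table.reference_copies)
            if sid == ref:
                F, p2, p1 = 1.0, 1.0, 1.0
            else:
                F, p2, p1 = variance_f_test(rep_estimates(merged, dct_ref), ref_reps)
            rows.append((sid, target, dct, dct - dct_ref, rq, cn, F, p2, p1))
    return pd.DataFrame(
        rows,
        columns=[
            "sample_id", "target_id", "delta_ct", "delta_delta_ct",
            "rq", "copy_number", "F", "p_two_sided", "p_greater_variance",
        ],
    )


def simulate_ct_table(
    copy_numbers: dict[str, dict[str, float]],
    reference_sample_id: str,
    control_id: str = "control",
    control_copies: int = 1,
    reference_copies: int = 2,
    n_replicates: int = 3,
    ct_noise_sd: float = 0.1,
    base_ct: float = 22.0,
    seed: int | None = None,
) -> CtTable:
    """Generate a Ct table from known copy numbers at perfect efficiency.

    ``copy_numbers[sample][target]`` is the true copy count; the control
    amplicon has ``control_copies`` in every sample. Ct values follow
    Ct = base - log2(template amount) + Gaussian noise (sd ``ct_noise_sd``).
    """
    rng = np.random.default_rng(seed)
    rows = []
    for sid, targets in copy_numbers.items():
        amounts = dict(targets)
        amounts[control_id] = control_copies
        for tid, cn in amounts.items():
            if cn <= 0:
                raise ValueError("simulated copy numbers must be > 0")
            for rep in range(n_replicates):
                ct = base_ct - np.log2(cn) + rng.normal(0, ct_noise_sd)
                rows.append((sid, tid, control_id, rep, ct))
    return CtTable(
        data=pd.DataFrame(rows, columns=CT_COLUMNS),
        reference_sample_id=reference_sample_id,
        control_copies=control_copies,
        reference_copies=reference_copies,
    )
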