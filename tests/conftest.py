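import numpy as np
import pytest

import oxispec as ox


@pytest.fixture(scope="session")
def default_dataset():
    """Full 144-row shelf-life dataset from the default generator."""
    design, chem, spectra = ox.simulate_dataset(seed=7)
    return design, chem, spectra


@pytest.fixture(scope="session")
def preprocessed(default_dataset):
    design, chem, spectra = default_dataset
    return design, chem, ox.preprocess(spectra)


@pytest.fixture(scope="session")
def small_design():
    """3 times x 2 temperatures x 3 materials x 2 replicates = 36 rows."""
    spec = ox.DesignSpec(
        time_levels=(15, 90, 270),
        temperature_levels=(10, 25),
        material_levels=("PP", "CG", "AGA"),
        n_replicates=2,
    )
    return ox.generate_design(spec)


def brute_force_anova_ssq(y: np.ndarray, design) -> dict:
    """Three-way fixed-effects sums of squares by explicit cell-mean arithmetic.

    Independent oracle: plain loops over levels, no shared code with the
    package's decomposition.
    """
    y = np.asarray(y, float)
    t = design["time"].to_numpy()
    T = design["temperature"].to_numpy()
    m = design["material"].to_numpy()
    grand = y.mean()

    def mean_where(mask):
        return y[mask].mean()

    ssq = {}
    factors = {"time": t, "temp": T, "mat": m}
    for name, lab in factors.items():
        s = 0.0
        for lv in np.unique(lab):
            mask = lab == lv
            s += mask.sum() * (mean_where(mask) - grand) ** 2
        ssq[name] = s
    for name, (la, lb) in {
        "time:temp": (t, T), "temp:mat": (T, m), "mat:time": (m, t)
    }.items():
        s = 0.0
        for a in np.unique(la):
            for b in np.unique(lb):
                mask = (la == a) & (lb == b)
                cell = mean_where(mask)
                s += mask.sum() * (
                    cell - mean_where(la == a) - mean_where(lb == b) + grand
                ) ** 2
        ssq[name] = s
    total = float(np.sum((y - grand) ** 2))
    ssq["residual"] = total - sum(ssq.values())
    return ssq
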