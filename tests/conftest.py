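import numpy as np
import pytest

from gdmprs.cohort import GenotypeMatrix, VariantRecord


@pytest.fixture
def tiny_genotypes() -> GenotypeMatrix:
    """3 subjects x 2 variants, one missing call."""
    variants = [
        VariantRecord("rs1", "1", 1000, "A", "G", 0.25),
        VariantRecord("rs2", "2", 2000, "C", "T", 0.40),
    ]
    dosages = np.array([[0.0, 2.0], [1.0, np.nan], [2.0, 1.0]])
    return GenotypeMatrix(variants, dosages, ["a", "b", "c"])


def textbook_irls(x: np.ndarray, y: np.ndarray, tol: float = 1e-12,
                  max_iter: int = 200) -> np.ndarray:
    """Independent textbook IRLS for logistic regression (design x incl.
    intercept); used as an oracle against the package's fits."""
    beta = np.zeros(x.shape[1])
    for _ in range(max_iter):
        eta = x @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1.0 - mu)
        z = eta + (y - mu) / w
        wx = x * w[:, None]
        new = np.linalg.solve(x.T @ wx, wx.T @ z)
        if np.max(np.abs(new - beta)) < tol:
            return new
        beta = new
    return beta
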