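"""Independent brute-force oracle for the fully within-subject ANOVA.

Textbook marginal-mean formulas written out term by term for the
2x2x2-by-subject layout — deliberately a separate code path from the
package's generic subset machinery.
"""

import numpy as np
from scipy import stats


def brute_rm_anova(y):
    """y[s, a, b, c] -> dict effect -> (SS_eff, SS_err, F, p)."""
    y = np.asarray(y, dtype=float)
    n = y.shape[0]
    g = y.mean()
    mS = y.mean(axis=(1, 2, 3))
    mA = y.mean(axis=(0, 2, 3))
    mB = y.mean(axis=(0, 1, 3))
    mC = y.mean(axis=(0, 1, 2))
    mSA = y.mean(axis=(2, 3))
    mSB = y.mean(axis=(1, 3))
    mSC = y.mean(axis=(1, 2))
    mAB = y.mean(axis=(0, 3))
    mAC = y.mean(axis=(0, 2))
    mBC = y.mean(axis=(0, 1))
    mSAB = y.mean(axis=3)
    mSAC = y.mean(axis=2)
    mSBC = y.mean(axis=1)
    mABC = y.mean(axis=0)

    ss = {}
    ss["A"] = 4 * n * np.sum((mA - g) ** 2)
    ss["B"] = 4 * n * np.sum((mB - g) ** 2)
    ss["C"] = 4 * n * np.sum((mC - g) ** 2)
    ss["AxS"] = 4 * np.sum((mSA - mS[:, None] - mA[None, :] + g) ** 2)
    ss["BxS"] = 4 * np.sum((mSB - mS[:, None] - mB[None, :] + g) ** 2)
    ss["CxS"] = 4 * np.sum((mSC - mS[:, None] - mC[None, :] + g) ** 2)
    ss["AB"] = 2 * n * np.sum((mAB - mA[:, None] - mB[None, :] + g) ** 2)
    ss["AC"] = 2 * n * np.sum((mAC - mA[:, None] - mC[None, :] + g) ** 2)
    ss["BC"] = 2 * n * np.sum((mBC - mB[:, None] - mC[None, :] + g) ** 2)
    ss["ABxS"] = 2 * np.sum(
        (
            mSAB
            - mSA[:, :, None]
            - mSB[:, None, :]
            - mAB[None]
            + mS[:, None, None]
            + mA[None, :, None]
            + mB[None, None, :]
            - g
        )
        ** 2
    )
    ss["ACxS"] = 2 * np.sum(
        (
            mSAC
            - mSA[:, :, None]
            - mSC[:, None, :]
            - mAC[None]
            + mS[:, None, None]
            + mA[None, :, None]
            + mC[None, None, :]
            - g
        )
        ** 2
    )
    ss["BCxS"] = 2 * np.sum(
        (
            mSBC
            - mSB[:, :, None]
            - mSC[:, None, :]
            - mBC[None]
            + mS[:, None, None]
            + mB[None, :, None]
            + mC[None, None, :]
            - g
        )
        ** 2
    )
    ss["ABC"] = n * np.sum(
        (
            mABC
            - mAB[:, :, None]
            - mAC[:, None, :]
            - mBC[None]
            + mA[:, None, None]
            + mB[None, :, None]
            + mC[None, None, :]
            - g
        )
        ** 2
    )
    ss["ABCxS"] = np.sum(
        (
            y
            - mSAB[:, :, :, None]
            - mSAC[:, :, None, :]
            - mSBC[:, None, :, :]
            - mABC[None]
            + mSA[:, :, None, None]
            + mSB[:, None, :, None]
            + mSC[:, None, None, :]
            + mAB[None, :, :, None]
            + mAC[None, :, None, :]
            + mBC[None, None, :, :]
            - mS[:, None, None, None]
            - mA[None, :, None, None]
            - mB[None, None, :, None]
            - mC[None, None, None, :]
            + g
        )
        ** 2
    )

    out = {}
    pairs = {
        "A": "AxS", "B": "BxS", "C": "CxS",
        "AB": "ABxS", "AC": "ACxS", "BC": "BCxS",
        "ABC": "ABCxS",
    }
    for eff, err in pairs.items():
        F = (ss[eff] / 1.0) / (ss[err] / (n - 1))
        out[eff] = (ss[eff], ss[err], F, float(stats.f.sf(F, 1, n - 1)))
    return out
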