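"""Published per-volume error tables for the two public liver CT benchmarks.

These are the five-metric errors (VOE %, RVD %, ASD mm, RMSD mm, MSD mm)
reported per test volume on the MICCAI 2007 liver segmentation challenge
training set and on the 3D-IRCADb database. They serve as inputs to the
scoring stack (``swarmcut score-table`` recomputes every total score from its
error row), not as segmentation outputs of this package.
"""

from __future__ import annotations

from .metrics import DEFAULT_REFERENCE, ErrorMetrics, total_score

__all__ = ["MICCAI_ERRORS", "IRCAD_ERRORS", "score_table"]

# volume id -> (VOE %, RVD %, ASD mm, RMSD mm, MSD mm)
MICCAI_ERRORS: dict[int, tuple[float, float, float, float, float]] = {
    1: (8.28, 0.43, 1.33, 1.98, 16.8),
    2: (5.43, 1.32, 0.95, 1.69, 17.52),
    3: (6.47, 1.74, 1.08, 2.43, 22.75),
    4: (6.73, 0.88, 0.42, 0.95, 15.14),
    5: (5.8, 0.34, 0.57, 1.09, 13.16),
    6: (7.15, 0.54, 0.96, 1.65, 17.1),
    7: (5.12, 0.45, 0.76, 1.28, 13.35),
    8: (6.28, 0.9, 0.92, 1.49, 17.84),
    9: (4.16, 3.53, 0.72, 1.26, 16.7),
    10: (5.25, 0.73, 0.93, 2.23, 19.8),
}

IRCAD_ERRORS: dict[int, tuple[float, float, float, float, float]] = {
    1: (5.1, 2.5, 0.7, 1.4, 16.1),
    2: (5.4, 1.4, 0.7, 1.7, 21.4),
    3: (4.9, 0.1, 0.7, 1.3, 16.2),
    4: (5.7, 2.3, 0.8, 1.8, 19.6),
    5: (6.1, 0.1, 1.2, 2.5, 28.3),
    6: (5.2, 0.6, 0.7, 1.8, 21.4),
    7: (4.09, 0.5, 0.6, 1.5, 15.9),
    8: (5.9, 1.8, 0.9, 1.8, 19.2),
    9: (4.8, 3.7, 0.5, 0.8, 16.1),
    10: (6.4, 1.04, 0.8, 1.7, 13.4),
}

# total scores as printed alongside the error rows, for cross-checking
MICCAI_PUBLISHED_SCORES: dict[int, float] = {
    1: 76.5, 2: 80.3, 3: 74.96, 4: 85.08, 5: 85.77,
    6: 79.96, 7: 84.65, 8: 80.7, 9: 81.5, 10: 79.07,
}
IRCAD_PUBLISHED_SCORES: dict[int, float] = {
    1: 81.73, 2: 80.44, 3: 84.69, 4: 78.94, 5: 74.74,
    6: 81.17, 7: 84.92, 8: 78.92, 9: 83.35, 10: 81.65,
}


def score_table(errors: dict[int, tuple[float, float, float, float, float]], refs=DEFAULT_REFERENCE):
    """Recompute every total score of a benchmark error table; returns {id: total}."""
    return {
        vid: total_score(ErrorMetrics(*row), refs).total for vid, row in errors.items()
    }
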