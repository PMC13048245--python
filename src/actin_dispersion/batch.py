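"""Batch processing and group comparison over files.

One CSV row per image; per-image failures (unreadable file, no fibers,
no nuclei) are logged and skipped so a single bad field does not abort a
plate's worth of micrographs.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import pandas as pd

from .config import RunConfig
from .dispersion import compare_groups, compute_dispersion
from .errors import ActinDispersionError, DataError
from .image_io import load_image

logger = logging.getLogger("actin_dispersion")

IMAGE_SUFFIXES = (".png", ".tif", ".tiff", ".jpg", ".jpeg")

RESULT_COLUMNS = ["path", "n_points", "n_nuclei", "n_bins", "etp_nats", "dsp", "param_hash"]


def run_batch(input_dir: str | Path, config: RunConfig | None = None, output: str | Path | None = None) -> pd.DataFrame:
    """Compute dsp for every readable image in ``input_dir``.

    Returns the per-image results table (and writes it as CSV when
    ``output`` is given).  Raises :class:`DataError` for an input
    directory with no candidate images; individual failures are logged
    with their stage and reason.
    """
    cfg = config or RunConfig()
    input_dir = Path(input_dir)
    paths = sorted(p for p in input_dir.iterdir() if p.suffix.lower() in IMAGE_SUFFIXES)
    if not paths:
        raise DataError(f"no images found in {input_dir!s}")
    phash = cfg.param_hash()
    rows = []
    for path in paths:
        try:
            img = load_image(path)
            res = compute_dispersion(img, cfg)
        except (ActinDispersionError, IOError) as exc:
            logger.warning("skipping %s: %s: %s", path.name, type(exc).__name__, exc)
            continue
        logger.info("%s: dsp=%.4f (%d edges, %d nuclei)", path.name, res.dsp, res.n_points, res.n_nuclei)
        rows.append(
            {
                "path": str(path),
                "n_points": res.n_points,
                "n_nuclei": res.n_nuclei,
                "n_bins": res.n_bins,
                "etp_nats": res.etp,
                "dsp": res.dsp,
                "param_hash": phash,
            }
        )
    table = pd.DataFrame(rows, columns=RESULT_COLUMNS)
    if output is not None:
        table.to_csv(output, index=False)
    return table


def run_compare(
    group_a_csv: str | Path,
    group_b_csv: str | Path,
    output: str | Path | None = None,
    name_a: str = "group_a",
    name_b: str = "group_b",
) -> dict:
    """Unpaired Student t test between the ``dsp`` columns of two result CSVs."""
    values = []
    for path in (group_a_csv, group_b_csv):
        frame = pd.read_csv(path)
        if "dsp" not in frame.columns:
            raise DataError(f"{path!s} has no 'dsp' column")
        col = frame["dsp"].dropna()
        if len(col) < 2:
            raise DataError(f"{path!s} has fewer than 2 dsp values")
        values.append(col.to_numpy())
    stats = compare_groups(values[0], values[1])
    report = {"group_a": name_a, "group_b": name_b, **stats}
    if output is not None:
        Path(output).write_text(json.dumps(report, indent=1))
    return report
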