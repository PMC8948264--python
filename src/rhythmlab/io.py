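"""Readers, writers, configuration, and actogram rendering.

Formats
-------
* TriKinetics DAM monitor files: 42 tab-separated fields per row (reading
  index, date, time, status code, six device fields, then 32 channel
  counts), one row per minute.  Rows whose status is not 1 are masked to
  zero counts and reported.
* Activity CSV (wheel-running dialect): ``#``-prefixed metadata lines
  (species, bin_minutes, start), a header row of subject ids, then one row
  per bin with the bin start hour in column 1.  Round-trips bit-exactly.
* MaxQuant proteinGroups TSV: per-sample ``LFQ intensity <sample>`` columns;
  flag columns ``Only identified by site`` / ``Reverse`` / ``Potential
  contaminant`` hold ``+`` when set; 0 or blank intensity means missing.
"""

from __future__ import annotations

import datetime as _dt
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .proteomics import ProteinTable
from .rhythms import ActivityTrace
from .schedule import LightSchedule

__all__ = [
    "read_dam_monitor",
    "read_activity_csv",
    "write_activity_csv",
    "read_protein_groups",
    "write_protein_groups",
    "render_actogram",
    "PipelineConfig",
    "load_config",
]

DAM_N_FIELDS = 42
DAM_N_CHANNELS = 32


def read_dam_monitor(path, bin_minutes: float = 1.0, start: float = 0.0,
                     return_gaps: bool = False):
    """Read a TriKinetics DAM monitor file into 32 fly activity traces.

    Rows with a status code other than 1 are treated as gaps: their counts
    are masked to zero and their row indices reported (with
    ``return_gaps=True`` the gap list is returned alongside the traces).
    """
    path = Path(path)
    rows, stamps, gaps = [], [], []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != DAM_N_FIELDS:
                raise ValueError(
                    f"{path.name}:{ln}: expected {DAM_N_FIELDS} tab-separated "
                    f"fields, got {len(fields)}")
            try:
                stamp = _dt.datetime.strptime(f"{fields[1]} {fields[2]}",
                                              "%d %b %y %H:%M:%S")
            except ValueError as e:
                raise ValueError(f"{path.name}:{ln}: bad timestamp: {e}") from None
            try:
                counts = [int(c) for c in fields[-DAM_N_CHANNELS:]]
            except ValueError:
                raise ValueError(f"{path.name}:{ln}: non-integer count") from None
            if any(c < 0 for c in counts):
                raise ValueError(f"{path.name}:{ln}: negative count")
            status = fields[3]
            if status != "1":
                gaps.append(ln)
                counts = [0] * DAM_N_CHANNELS
            if stamps and stamp <= stamps[-1]:
                raise ValueError(f"{path.name}:{ln}: non-monotonic timestamp")
            stamps.append(stamp)
            rows.append(counts)
    if not rows:
        raise ValueError(f"{path.name}: empty monitor file")
    arr = np.asarray(rows)
    traces = [ActivityTrace(f"ch{c + 1:02d}", "fly", bin_minutes, start, arr[:, c])
              for c in range(DAM_N_CHANNELS)]
    return (traces, gaps) if return_gaps else traces


def write_activity_csv(traces: list[ActivityTrace], path) -> None:
    """Write a cohort of equally binned traces to the activity CSV dialect."""
    if not traces:
        raise ValueError("no traces to write")
    t0 = traces[0]
    for tr in traces:
        if (tr.species != t0.species or tr.bin_minutes != t0.bin_minutes
                or tr.start != t0.start or tr.n_bins != t0.n_bins):
            raise ValueError("all traces in one file must share species, bin "
                             "width, start and length")
    with open(path, "w") as fh:
        fh.write(f"# species: {t0.species}\n")
        fh.write(f"# bin_minutes: {t0.bin_minutes!r}\n")
        fh.write(f"# start: {t0.start!r}\n")
        fh.write("hour," + ",".join(tr.subject_id for tr in traces) + "\n")
        hours = t0.bin_starts()
        mat = np.column_stack([tr.counts for tr in traces])
        for i in range(t0.n_bins):
            fh.write(f"{hours[i]!r}," + ",".join(str(int(c)) for c in mat[i]) + "\n")


def read_activity_csv(path) -> list[ActivityTrace]:
    """Read the activity CSV dialect written by :func:`write_activity_csv`."""
    path = Path(path)
    meta = {}
    with open(path) as fh:
        lines = fh.read().splitlines()
    i = 0
    while i < len(lines) and lines[i].startswith("#"):
        key, _, val = lines[i][1:].partition(":")
        meta[key.strip()] = val.strip()
        i += 1
    if i >= len(lines) or not lines[i].startswith("hour"):
        raise ValueError(f"{path.name}: missing 'hour' header row")
    ids = lines[i].split(",")[1:]
    if not ids:
        raise ValueError(f"{path.name}: no subject columns")
    n_cols = len(ids) + 1
    counts = []
    for ln, line in enumerate(lines[i + 1:], start=i + 2):
        if not line:
            continue
        cells = line.split(",")
        if len(cells) != n_cols:
            raise ValueError(f"{path.name}:{ln}: ragged row "
                             f"({len(cells)} cells, expected {n_cols})")
        vals = [int(c) for c in cells[1:]]
        if any(v < 0 for v in vals):
            raise ValueError(f"{path.name}:{ln}: negative count")
        counts.append(vals)
    if not counts:
        raise ValueError(f"{path.name}: no data rows")
    arr = np.asarray(counts)
    species = meta.get("species", "mouse")
    bin_minutes = float(meta.get("bin_minutes", 6.0))
    start = float(meta.get("start", 0.0))
    return [ActivityTrace(ids[c], species, bin_minutes, start, arr[:, c])
            for c in range(len(ids))]


# ---------------------------------------------------------------------------
# proteinGroups TSV
# ---------------------------------------------------------------------------

_PG_FLAG_MAP = {
    "Only identified by site": "only_identified_by_site",
    "Reverse": "reverse",
    "Potential contaminant": "potential_contaminant",
}
_LFQ_PREFIX = "LFQ intensity "


def read_protein_groups(path) -> ProteinTable:
    """Read a MaxQuant-style proteinGroups TSV into a raw-scale ProteinTable.

    Intensity 0 or blank means a missing cell (the MaxQuant convention);
    flag cells are true when they hold ``+``.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    lfq_cols = [c for c in df.columns if c.startswith(_LFQ_PREFIX)]
    if not lfq_cols:
        raise ValueError("no 'LFQ intensity <sample>' columns found")
    id_col = "Protein IDs" if "Protein IDs" in df.columns else df.columns[0]
    index = df[id_col].astype(str)
    intens = df[lfq_cols].apply(pd.to_numeric, errors="coerce")
    intens = intens.where(intens > 0)  # 0 or blank -> missing
    intens.columns = [c[len(_LFQ_PREFIX):] for c in lfq_cols]
    intens.index = index
    flags = pd.DataFrame(False, index=index, columns=list(_PG_FLAG_MAP.values()))
    for src, dst in _PG_FLAG_MAP.items():
        if src in df.columns:
            flags[dst] = (df[src].fillna("") == "+").to_numpy()
    return ProteinTable(intens, flags, log2_scale=False)


def write_protein_groups(table: ProteinTable, path) -> None:
    """Write a ProteinTable as a MaxQuant-style proteinGroups TSV."""
    if table.log2_scale:
        raise ValueError("write raw-scale tables only")
    df = pd.DataFrame({"Protein IDs": table.intensities.index})
    for s in table.samples:
        col = table.intensities[s].to_numpy(float)
        df[_LFQ_PREFIX + s] = np.where(np.isnan(col), 0.0, col)
    for src, dst in _PG_FLAG_MAP.items():
        df[src] = np.where(table.flags[dst].to_numpy(), "+", "")
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# actogram rendering
# ---------------------------------------------------------------------------

def render_actogram(trace: ActivityTrace, folding_period: float = 24.0,
                    double_plot: bool = True, schedule: LightSchedule | None = None,
                    out=None):
    """Raster (double-)plot of successive cycles with light phases shaded.

    Returns the matplotlib figure; saves to ``out`` when given.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    bh = trace.bin_hours
    bins_per = int(round(folding_period / bh))
    n_rows = trace.n_bins // bins_per
    if n_rows < 1:
        raise ValueError("trace shorter than one folding period")
    width = 2 if double_plot else 1
    fig, axes = plt.subplots(n_rows, 1, figsize=(8, 0.28 * n_rows + 0.8),
                             sharex=True, squeeze=False)
    peak = max(1.0, float(trace.counts.max()))
    for r in range(n_rows):
        ax = axes[r, 0]
        segs = []
        for k in range(width):
            row = r + k
            if row < trace.n_bins // bins_per or (row * bins_per + bins_per
                                                  <= trace.n_bins):
                seg = trace.counts[row * bins_per:(row + 1) * bins_per]
            else:
                seg = np.zeros(bins_per, dtype=int)
            segs.append(seg)
        y = np.concatenate(segs) / peak
        x = np.arange(y.size) * bh
        if schedule is not None:
            t0 = trace.start + r * folding_period
            lux = np.asarray(schedule.light_at(t0 + x + bh / 2))
            ax.fill_between(x, 0, 1, where=lux > 0, color="#fff3b0", step="post")
        ax.bar(x, y, width=bh, align="edge", color="black")
        ax.set_ylim(0, 1)
        ax.set_yticks([])
        ax.set_ylabel(f"{r}", rotation=0, ha="right", va="center", fontsize=6)
    axes[-1, 0].set_xlabel("hours")
    axes[0, 0].set_title(f"{trace.subject_id} (fold {folding_period:g} h)",
                         fontsize=9)
    fig.tight_layout(h_pad=0.0)
    if out is not None:
        fig.savefig(out, dpi=120)
        plt.close(fig)
    return fig


# ---------------------------------------------------------------------------
# pipeline configuration
# ---------------------------------------------------------------------------

_CONFIG_DEFAULTS: dict = {
    "seed": 0,
    "outdir": "results",
    "schedule": {"paradigm": "LD", "days": 14},
    "detection": {"onset_frac": 0.20, "offset_frac": 0.05, "smooth_minutes": None,
                  "folding_period": 24.0},
    "classification": {"fft_threshold": 0.01, "alpha": 0.05,
                       "period_sd_threshold": 0.5,
                       "short_band": [20.0, 22.0], "long_band": [22.5, 28.0]},
    "simulation": {"species": "mouse", "n_subjects": 10, "bin_minutes": None,
                   "duration_hours": None},
    "proteomics": {"min_valid": 4, "downshift": 1.8, "width": 0.3, "s0": 0.1,
                   "fdr": 0.05, "min_per_term": 3, "enrich_alpha": 0.05},
}


class PipelineConfig(dict):
    """Validated pipeline configuration with materialized defaults."""

    @classmethod
    def from_mapping(cls, data: dict | None) -> "PipelineConfig":
        data = data or {}
        out = cls()
        unknown = set(data) - set(_CONFIG_DEFAULTS)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key, default in _CONFIG_DEFAULTS.items():
            if isinstance(default, dict):
                sub = dict(default)
                extra = data.get(key, {}) or {}
                unknown = set(extra) - set(default)
                if unknown and key != "schedule" and key != "simulation":
                    raise ValueError(f"unknown config keys in {key!r}: "
                                     f"{sorted(unknown)}")
                sub.update(extra)
                out[key] = sub
            else:
                out[key] = data.get(key, default)
        return out

    def write_resolved(self, outdir) -> Path:
        """Persist the fully resolved config next to the outputs."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        p = outdir / "resolved_config.yml"
        with open(p, "w") as fh:
            yaml.safe_dump(dict(self), fh, sort_keys=True)
        return p


def load_config(path) -> PipelineConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return PipelineConfig.from_mapping(data)
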