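"""Minimal interactive layer over the library.

The application is a pure state machine: an :class:`AppState` names the
current sample, variable, scale and styling, plus the pending spot
selection and the annotation table; every view is a pure function of that
state, rendered by delegating to :mod:`viz_static`. A thin stdlib HTTP
wrapper (`App.serve`) exposes the current view as a PNG for browsing;
the contractual surface is the state transitions and the PNG/CSV download
payloads, both of which reuse the core modules — no plotting or QC logic
is duplicated here.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace

from . import annotation as ann_mod
from . import qc_norm, spaceranger_io, viz_static
from .core_model import SpatialDataset
from .palettes import SCALE_NAMES, get_scale


@dataclass
class AppState:
    """Serializable UI state; every view derives from it deterministically."""

    sample_id: str
    variable: str
    kind: str  # continuous | categorical
    scale_name: str = "viridis"
    scale_reversed: bool = False
    point_size_multiplier: float = 1.0
    spot_alpha: float = 1.0
    image_ops: tuple = ()
    view: str = "single"  # single | side_by_side | grid
    selection: tuple = ()
    annotations: ann_mod.AnnotationTable = field(
        default_factory=ann_mod.AnnotationTable)


def _initial_state(dataset: SpatialDataset) -> AppState:
    first = dataset.samples[0]
    if first.spot_covariates:
        var = sorted(first.spot_covariates)[0]
        import numpy as np
        vec = np.asarray(first.spot_covariates[var])
        kind = ("continuous" if np.issubdtype(vec.dtype, np.number)
                else "categorical")
    else:
        var = "sum_umi"
        kind = "continuous"
        for s in dataset.samples:
            qc_norm.attach_qc_covariates(s)
    return AppState(sample_id=first.sample_id, variable=var, kind=kind)


class App:
    """Stateful façade: state transitions + renders + downloads."""

    def __init__(self, dataset: SpatialDataset, state: AppState):
        self.dataset = dataset
        self.state = state

    # -- state transitions -------------------------------------------------

    def set_variable(self, variable: str, kind: str) -> None:
        sample = self.dataset.get_sample(self.state.sample_id)
        try:  # validate before committing; errors leave the state unchanged
            if kind == "continuous":
                viz_static.resolve_continuous(sample, variable)
            else:
                viz_static.resolve_categorical(sample, variable)
        except (KeyError, ValueError) as exc:
            raise ValueError(f"cannot display {variable!r}: {exc}") from exc
        self.state = replace(self.state, variable=variable, kind=kind)

    def set_sample(self, sample_id: str) -> None:
        self.dataset.get_sample(sample_id)  # raises if unknown
        self.state = replace(self.state, sample_id=sample_id, selection=())

    def set_scale(self, name: str, reversed: bool = False) -> None:
        if name not in SCALE_NAMES:
            raise ValueError(f"unknown scale {name!r}; valid: "
                             f"{', '.join(SCALE_NAMES)}")
        self.state = replace(self.state, scale_name=name,
                             scale_reversed=reversed)

    def apply_selection(self, polygon) -> None:
        """Replace the pending selection with the spots inside a polygon."""
        sample = self.dataset.get_sample(self.state.sample_id)
        if not polygon:
            self.state = replace(self.state, selection=())
            return
        selected = ann_mod.select_in_polygon(sample, polygon, "lowres")
        self.state = replace(self.state, selection=tuple(selected))

    def label_selection(self, label: str) -> None:
        sample = self.dataset.get_sample(self.state.sample_id)
        table = ann_mod.label_spots(self.state.annotations, sample,
                                    list(self.state.selection), label)
        self.state = replace(self.state, annotations=table)

    # -- rendering ---------------------------------------------------------

    def _spec(self) -> viz_static.PlotSpec:
        st = self.state
        return viz_static.PlotSpec(
            variable=st.variable, kind=st.kind,
            point_size_multiplier=st.point_size_multiplier,
            spot_alpha=st.spot_alpha,
            scale=get_scale(st.scale_name, st.scale_reversed))

    def render(self):
        """Render the current view as a matplotlib figure."""
        st = self.state
        spec = self._spec()
        if st.view == "grid":
            return viz_static.plot_grid(self.dataset, spec)
        sample = self.dataset.get_sample(st.sample_id)
        if st.image_ops:
            from . import image_ops
            img = sample.images.get(spec.resolution_tag)
            edited = image_ops.apply_ops(img, st.image_ops) if img else None
        else:
            edited = None
        if st.view == "side_by_side":
            return viz_static.plot_side_by_side(sample, spec,
                                                left_image=edited)
        if st.kind == "continuous":
            return viz_static.plot_continuous(sample, spec)
        return viz_static.plot_categorical(sample, spec)

    # -- downloads ---------------------------------------------------------

    def download(self, what: str) -> bytes:
        """Export the current view (png) or result tables (csv) as bytes."""
        import tempfile

        if what == "png":
            fig = self.render()
            buf = io.BytesIO()
            fig.savefig(buf, format="png", dpi=120)
            import matplotlib.pyplot as plt
            plt.close(fig)
            return buf.getvalue()
        if what == "annotation_csv":
            with tempfile.NamedTemporaryFile("r", suffix=".csv") as tmp:
                spaceranger_io.write_annotations(self.state.annotations,
                                                 tmp.name)
                return open(tmp.name, "rb").read()
        if what == "results_csv":
            sample = self.dataset.get_sample(self.state.sample_id)
            qc = qc_norm.compute_qc(sample)
            with tempfile.NamedTemporaryFile("r", suffix=".csv") as tmp:
                spaceranger_io.write_results_csv(qc.to_dataframe(), tmp.name)
                return open(tmp.name, "rb").read()
        raise ValueError(f"unknown download kind {what!r}; "
                         "valid: png, annotation_csv, results_csv")

    # -- serving -----------------------------------------------------------

    def serve(self, port: int = 8080) -> None:  # pragma: no cover
        """Serve the current view over HTTP (GET / → PNG) until interrupted."""
        from http.server import BaseHTTPRequestHandler, HTTPServer

        app = self

        class Handler(BaseHTTPRequestHandler):
            def do_GET(self):
                payload = app.download("png")
                self.send_response(200)
                self.send_header("Content-Type", "image/png")
                self.send_header("Content-Length", str(len(payload)))
                self.end_headers()
                self.wfile.write(payload)

            def log_message(self, *args):
                pass

        HTTPServer(("127.0.0.1", port), Handler).serve_forever()


def build_app(dataset: SpatialDataset, config: dict | None = None) -> App:
    """Build the interactive app with a deterministic initial state.

    Initial state: first sample, first covariate (sorted), defaults
    elsewhere; ``config`` keys override matching AppState fields.
    """
    if not dataset.samples:
        raise ValueError("cannot build an app over an empty dataset")
    state = _initial_state(dataset)
    if config:
        state = replace(state, **config)
    return App(dataset, state)
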