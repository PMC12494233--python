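"""Command-line interface.

Thin wrappers over the library pipelines: nuclei segmentation, positive
pixel counting, region feature extraction, and segmentation evaluation.
Exit codes: 0 success, 1 runtime failure, 2 usage error.  Every command
logs its version, parameters, and input digests as plain ``key=value``
lines on stdout.
"""

from __future__ import annotations

import sys

import click
import numpy as np
import pandas as pd

from .. import __version__
from ..color.deconvolution import DEFAULT_HE_MATRIX, StainMatrix, color_deconvolution
from ..features import (
    compute_fsd_features,
    compute_gradient_features,
    compute_haralick_features,
    compute_intensity_features,
    compute_morphometry_features,
)
from ..segmentation.ppc import PPCParams, count_image, count_slide
from .io import (
    file_digest,
    read_image,
    read_json,
    read_label_tiff,
    write_json,
    write_label_tiff,
)
from .metrics import evaluate_segmentation
from .pipeline import NUCLEI_ALGORITHMS, nuclei_annotation, segment_nuclei_tiled
from .tiles import TileGrid, iterate_tiles


def _log(**kwargs):
    for k, v in kwargs.items():
        click.echo(f"{k}={v}")


@click.group()
@click.version_option(__version__)
def main():
    """Histology image analysis pipelines."""


def _load_stain_matrix(path):
    if path is None:
        return DEFAULT_HE_MATRIX
    doc = read_json(path)
    return StainMatrix(np.array(doc["matrix"]), tuple(doc.get("names", ())))


@main.command()
@click.option("--input", "input_path", required=True, type=click.Path(exists=True))
@click.option("--algorithm", type=click.Choice(NUCLEI_ALGORITHMS), default="kofahi")
@click.option("--stain-matrix", "stain_path", type=click.Path(exists=True), default=None,
              help="JSON stain matrix; default is the standard H&E pair.")
@click.option("--r-min", type=float, default=3.0)
@click.option("--r-max", type=float, default=10.0)
@click.option("--min-distance", type=float, default=5.0)
@click.option("--density-threshold", type=float, default=0.1)
@click.option("--min-area", type=int, default=10)
@click.option("--tile-size", type=int, default=None)
@click.option("--overlap", type=int, default=None)
@click.option("--output-label", required=True, type=click.Path())
@click.option("--output-annotation", type=click.Path(), default=None)
def nuclei(input_path, algorithm, stain_path, r_min, r_max, min_distance,
           density_threshold, min_area, tile_size, overlap, output_label,
           output_annotation):
    """Detect and segment nuclei in an RGB raster."""
    try:
        _log(version=__version__, command="nuclei", input=input_path,
             input_sha256=file_digest(input_path), algorithm=algorithm,
             r_min=r_min, r_max=r_max, min_distance=min_distance,
             tile_size=tile_size, overlap=overlap)
        im = read_image(input_path)
        labels = segment_nuclei_tiled(
            im, tile_size=tile_size, overlap=overlap, algorithm=algorithm,
            stain_matrix=_load_stain_matrix(stain_path), r_min=r_min, r_max=r_max,
            min_distance=min_distance, density_threshold=density_threshold,
            min_area=min_area,
        )
        write_label_tiff(output_label, labels)
        _log(n_objects=int(labels.max()), output_label=output_label)
        if output_annotation:
            doc = nuclei_annotation(labels)
            with open(output_annotation, "w") as f:
                f.write(doc.to_json())
            _log(output_annotation=output_annotation)
    except (OSError, ValueError) as exc:
        click.echo(f"error: {exc}", err=True)
        sys.exit(1)


@main.command()
@click.option("--input", "input_path", required=True, type=click.Path(exists=True))
@click.option("--hue-value", type=float, default=0.05)
@click.option("--hue-width", type=float, default=0.15)
@click.option("--saturation-minimum", type=float, default=0.05)
@click.option("--intensity-upper-limit", type=float, default=245.0)
@click.option("--intensity-weak-threshold", type=float, default=175.0)
@click.option("--intensity-strong-threshold", type=float, default=100.0)
@click.option("--intensity-lower-limit", type=float, default=0.0)
@click.option("--tile-size", type=int, default=None)
@click.option("--output", "output_path", required=True, type=click.Path())
@click.option("--output-label", type=click.Path(), default=None)
def ppc(input_path, hue_value, hue_width, saturation_minimum,
        intensity_upper_limit, intensity_weak_threshold,
        intensity_strong_threshold, intensity_lower_limit, tile_size,
        output_path, output_label):
    """Count positively stained pixels (whole slide = merged tiles)."""
    try:
        params = PPCParams(
            hue_value=hue_value, hue_width=hue_width,
            saturation_minimum=saturation_minimum,
            intensity_upper_limit=intensity_upper_limit,
            intensity_weak_threshold=intensity_weak_threshold,
            intensity_strong_threshold=intensity_strong_threshold,
            intensity_lower_limit=intensity_lower_limit,
        )
        _log(version=__version__, command="ppc", input=input_path,
             input_sha256=file_digest(input_path), tile_size=tile_size)
        im = read_image(input_path)
        if tile_size:
            grid = TileGrid((tile_size, tile_size), overlap=0)
            result = count_slide((t for t, _ in iterate_tiles(im, grid)), params)
        else:
            result = count_image(im, params, return_label=output_label is not None)
            if output_label and result.label is not None:
                write_label_tiff(output_label, result.label)
        write_json(output_path, result.to_dict())
        _log(positive=result.positive, total=result.total, output=output_path)
    except (OSError, ValueError) as exc:
        click.echo(f"error: {exc}", err=True)
        sys.exit(1)


_FEATURE_GROUPS = {
    "intensity": lambda labels, inten: compute_intensity_features(labels, inten),
    "morphometry": lambda labels, inten: compute_morphometry_features(labels, inten),
    "gradient": lambda labels, inten: compute_gradient_features(labels, inten),
    "fsd": lambda labels, inten: compute_fsd_features(labels),
    "haralick": lambda labels, inten: compute_haralick_features(labels, inten),
}


@main.command()
@click.option("--input", "input_path", required=True, type=click.Path(exists=True))
@click.option("--labels", "labels_path", required=True, type=click.Path(exists=True))
@click.option("--groups", default="intensity,morphometry,gradient,fsd,haralick",
              help="Comma-separated feature groups to compute.")
@click.option("--channel", type=int, default=0,
              help="Deconvolved stain channel used as the intensity raster.")
@click.option("--output", "output_path", required=True, type=click.Path())
def features(input_path, labels_path, groups, channel, output_path):
    """Extract per-object features; writes CSV plus a column manifest."""
    try:
        _log(version=__version__, command="features", input=input_path,
             input_sha256=file_digest(input_path), labels=labels_path,
             labels_sha256=file_digest(labels_path), groups=groups)
        im = read_image(input_path)
        labels = read_label_tiff(labels_path)
        if im.shape[:2] != labels.shape:
            raise ValueError(
                f"image {im.shape[:2]} and labels {labels.shape} are misaligned"
            )
        inten = color_deconvolution(im, DEFAULT_HE_MATRIX)[..., channel] if im.ndim == 3 else im

        tables = []
        for g in [g.strip() for g in groups.split(",") if g.strip()]:
            if g not in _FEATURE_GROUPS:
                raise ValueError(f"unknown feature group {g!r}")
            tables.append(_FEATURE_GROUPS[g](labels, inten))
        table = pd.concat(tables, axis=1)
        table.to_csv(output_path)
        write_json(str(output_path) + ".manifest.json", {"columns": list(table.columns)})
        _log(n_objects=len(table), n_features=table.shape[1], output=output_path)
    except (OSError, ValueError) as exc:
        click.echo(f"error: {exc}", err=True)
        sys.exit(1)


@main.command()
@click.option("--pred", "pred_path", required=True, type=click.Path(exists=True))
@click.option("--truth", "truth_path", required=True, type=click.Path(exists=True))
@click.option("--output", "output_path", required=True, type=click.Path())
def evaluate(pred_path, truth_path, output_path):
    """Pixel-wise precision/recall/accuracy/F1/IoU of a label image."""
    try:
        pred = read_label_tiff(pred_path)
        truth = read_label_tiff(truth_path)
        report = evaluate_segmentation(pred, truth)
        write_json(output_path, report.to_dict())
        _log(version=__version__, command="evaluate", f1=report.f1, iou=report.iou)
    except (OSError, ValueError) as exc:
        click.echo(f"error: {exc}", err=True)
        sys.exit(1)


if __name__ == "__main__":
    main()
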