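"""Shared fixtures: tiny images, a DICOM series writer and the expensive
module-scoped campaign/phantom runs reused across test modules."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=25,
                          deadline=None)
settings.load_profile("ci")


@pytest.fixture
def ramp_image():
    """8x8x8 ramp with CA-1-like anisotropic spacing (0.5, 0.5, 0.4) mm."""
    from poroseg.imagepre import VolumetricImage

    data = np.arange(512, dtype=float).reshape(8, 8, 8)
    return VolumetricImage(data, (0.5, 0.5, 0.4), (1.0, -2.0, 3.0))


def write_dicom_slice(path, pixel_array, z, pixel_spacing=(0.5, 0.5)):
    """Write one minimal CT-like DICOM slice."""
    import pydicom
    from pydicom.dataset import FileDataset, FileMetaDataset
    from pydicom.uid import ExplicitVRLittleEndian, generate_uid

    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = pydicom.uid.CTImageStorage
    meta.MediaStorageSOPInstanceUID = generate_uid()
    meta.TransferSyntaxUID = ExplicitVRLittleEndian
    ds = FileDataset(str(path), {}, file_meta=meta, preamble=b"\0" * 128)
    ds.SOPClassUID = meta.MediaStorageSOPClassUID
    ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
    ds.Modality = "CT"
    ds.Rows, ds.Columns = pixel_array.shape
    ds.PixelSpacing = [str(pixel_spacing[0]), str(pixel_spacing[1])]
    ds.ImagePositionPatient = ["0", "0", f"{z:.6g}"]
    ds.ImageOrientationPatient = ["1", "0", "0", "0", "1", "0"]
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.BitsAllocated = 16
    ds.BitsStored = 16
    ds.HighBit = 15
    ds.PixelRepresentation = 0
    ds.PixelData = pixel_array.astype(np.uint16).tobytes()
    ds.save_as(str(path), enforce_file_format=True)


@pytest.fixture
def dicom_series_factory(tmp_path):
    """Factory writing an n-slice series, optionally with one slice missing."""

    def make(n_slices=6, drop_slice=None, dz=0.4):
        d = tmp_path / "series"
        d.mkdir(exist_ok=True)
        rng = np.random.default_rng(0)
        vol = rng.integers(0, 500, size=(6, 6, n_slices)).astype(np.uint16)
        for k in range(n_slices):
            if k == drop_slice:
                continue
            # data[i, j, k] -> slice array is (rows=j, cols=i)
            write_dicom_slice(d / f"slice_{k:03d}.dcm", vol[:, :, k].T, z=k * dz)
        return d, vol

    return make


# ---------------------------------------------------------------------------
# expensive shared runs (module-scoped via session cache)
# ---------------------------------------------------------------------------

@pytest.fixture(scope="session")
def numeric_campaign():
    """Reduced calibration campaign with 2-D numeric solves at 64 cells."""
    from poroseg.calibration import run_campaign

    df, fit = run_campaign(resolution=64)
    return df, fit


@pytest.fixture(scope="session")
def phantom_case():
    """Noisy 64^3 sphere-on-tube phantom (CNR 20) with its ground truth."""
    from poroseg.synthetic import aneurysm_phantom

    img, gt = aneurysm_phantom(tube_radius_mm=3.2, sac_radius_mm=6.0,
                               neck_offset_mm=7.0, shape=(64, 64, 64),
                               spacing_mm=0.5, noise_sd=10.0, seed=7)
    return img, gt


def phantom_config(output_dir) -> "PipelineConfig":
    from poroseg.workflow import PipelineConfig

    return PipelineConfig(coarse_range=(50.0, 250.0), i_fluid=200.0,
                          i_solid=0.0, target_spacing_mm=None, fluid="blood",
                          inlet_side="x-", outlet_side="x+",
                          output_dir=str(output_dir))


@pytest.fixture(scope="session")
def phantom_run(phantom_case, tmp_path_factory):
    """Full pipeline run on the noisy phantom, with C2M evaluation."""
    from poroseg.workflow import run_pipeline

    img, gt = phantom_case
    out = tmp_path_factory.mktemp("phantom_run")
    cfg = phantom_config(out)
    report = run_pipeline(cfg, image=img, reference_mesh=gt.mesh)
    return {"image": img, "gt": gt, "config": cfg, "report": report,
            "outdir": out}
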