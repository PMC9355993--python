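"""Lossless model archives: JSON metadata + binary arrays in HDF5.

One file stores either a fitted normative model, or a mixture model
point estimate optionally together with its retained MCMC draws. Round
trips are bit-exact for every scalar field and array. Truncated or
foreign files raise :class:`ArchiveIntegrityError`.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np

from .errors import ArchiveIntegrityError, SchemaError
from .mixture import MCMCSamples, MixtureModel
from .normative import NormativeModel

_FORMAT_VERSION = 1


def _check_finite(name: str, arr: np.ndarray) -> None:
    if not np.all(np.isfinite(arr)):
        raise SchemaError(f"array {name!r} contains non-finite values")


def _write_arrays(grp: h5py.Group, arrays: dict[str, np.ndarray]) -> None:
    for name, arr in arrays.items():
        _check_finite(name, np.asarray(arr))
        grp.create_dataset(name, data=np.asarray(arr))


def _model_arrays(model) -> dict[str, np.ndarray]:
    if isinstance(model, NormativeModel):
        return {
            "beta0": model.beta0, "beta_age": model.beta_age,
            "cohort_offsets": model.cohort_offsets,
            "var_cohort": model.var_cohort,
            "var_subject": model.var_subject,
            "var_resid": model.var_resid,
        }
    return {
        "pi": model.pi, "mu": model.mu, "Sigma": model.Sigma,
        "beta": model.beta, "sigma2": model.sigma2,
    }


def write_model_archive(
    model: NormativeModel | MixtureModel,
    path: str | Path,
    samples: MCMCSamples | None = None,
    config_hash: str | None = None,
) -> None:
    """Write a model (and optionally its retained draws) to ``path``.

    Covariance draws must be SPD and all fields finite; violations raise
    before anything is written.
    """
    if isinstance(model, NormativeModel):
        if samples is not None:
            raise SchemaError("normative models carry no MCMC samples")
        kind = "normative"
        meta = {
            "region_names": list(model.region_names),
            "cohort_ids": list(model.cohort_ids),
            "method": model.method,
        }
    elif isinstance(model, MixtureModel):
        kind = "mixture"
        np.linalg.cholesky(model.Sigma)   # SPD precondition
        meta = {
            "K": model.K, "trend_order": model.trend_order,
            "region_names": list(model.region_names),
            "fixed_covariates": list(model.fixed_covariates),
            "etiv_mean": model.etiv_mean, "etiv_sd": model.etiv_sd,
            "cov_center": [float(v) for v in model.cov_center],
        }
    else:
        raise SchemaError(f"cannot archive object of type {type(model)}")

    with h5py.File(path, "w") as fh:
        fh.attrs["kind"] = kind
        fh.attrs["format_version"] = _FORMAT_VERSION
        fh.attrs["meta"] = json.dumps(meta)
        if config_hash is not None:
            fh.attrs["config_hash"] = config_hash
        _write_arrays(fh.create_group("model"), _model_arrays(model))
        if samples is not None:
            smeta = {
                "subject_ids": list(samples.subject_ids),
                "n_iter": samples.n_iter, "burn_in": samples.burn_in,
                "thin": samples.thin, "seed": samples.seed,
            }
            grp = fh.create_group("samples")
            grp.attrs["meta"] = json.dumps(smeta)
            arrays = {
                "pi": samples.pi, "mu": samples.mu, "Sigma": samples.Sigma,
                "beta": samples.beta, "sigma2": samples.sigma2,
                "z": samples.z, "deviance": samples.deviance,
            }
            if samples.empty_fraction is not None:
                arrays["empty_fraction"] = samples.empty_fraction
            _write_arrays(grp, arrays)


def read_model_archive(
    path: str | Path,
) -> tuple[NormativeModel | MixtureModel, MCMCSamples | None]:
    """Read an archive written by :func:`write_model_archive`.

    Returns ``(model, samples)``; ``samples`` is None when none were
    stored (always, for normative models).
    """
    try:
        with h5py.File(path, "r") as fh:
            kind = fh.attrs["kind"]
            meta = json.loads(fh.attrs["meta"])
            m = {k: np.asarray(v) for k, v in fh["model"].items()}
            if kind == "normative":
                model: NormativeModel | MixtureModel = NormativeModel(
                    region_names=tuple(meta["region_names"]),
                    beta0=m["beta0"], beta_age=m["beta_age"],
                    cohort_ids=tuple(meta["cohort_ids"]),
                    cohort_offsets=m["cohort_offsets"],
                    var_cohort=m["var_cohort"],
                    var_subject=m["var_subject"],
                    var_resid=m["var_resid"],
                    method=meta["method"],
                )
            elif kind == "mixture":
                model = MixtureModel(
                    K=int(meta["K"]), trend_order=int(meta["trend_order"]),
                    region_names=tuple(meta["region_names"]),
                    fixed_covariates=tuple(meta["fixed_covariates"]),
                    etiv_mean=float(meta["etiv_mean"]),
                    etiv_sd=float(meta["etiv_sd"]),
                    cov_center=np.asarray(meta["cov_center"], float),
                    pi=m["pi"], mu=m["mu"], Sigma=m["Sigma"],
                    beta=m["beta"], sigma2=m["sigma2"],
                )
            else:
                raise ArchiveIntegrityError(f"unknown archive kind {kind!r}")
            samples = None
            if "samples" in fh:
                grp = fh["samples"]
                smeta = json.loads(grp.attrs["meta"])
                s = {k: np.asarray(v) for k, v in grp.items()}
                samples = MCMCSamples(
                    K=model.K, trend_order=model.trend_order,
                    region_names=tuple(meta["region_names"]),
                    fixed_covariates=tuple(meta["fixed_covariates"]),
                    etiv_mean=float(meta["etiv_mean"]),
                    etiv_sd=float(meta["etiv_sd"]),
                    cov_center=np.asarray(meta["cov_center"], float),
                    subject_ids=tuple(smeta["subject_ids"]),
                    pi=s["pi"], mu=s["mu"], Sigma=s["Sigma"],
                    beta=s["beta"], sigma2=s["sigma2"],
                    z=s["z"], deviance=s["deviance"],
                    n_iter=int(smeta["n_iter"]),
                    burn_in=int(smeta["burn_in"]),
                    thin=int(smeta["thin"]), seed=int(smeta["seed"]),
                    empty_fraction=s.get("empty_fraction"),
                )
            return model, samples
    except (OSError, KeyError, json.JSONDecodeError, ValueError) as exc:
        raise ArchiveIntegrityError(
            f"corrupt or unreadable model archive {path}: {exc}"
        ) from exc
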