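"""Saving and loading fitted posteriors as flat text artifacts.

A fit is persisted as three files sharing a prefix:

* ``<prefix>_draws.csv`` — long table (parameter, chain, iteration, value)
  of every scalar population parameter,
* ``<prefix>_meta.json`` — model/prior specification, chain layout and
  (optionally) the fitted subject ids,
* ``<prefix>_diagnostics.json`` — R-hat per parameter and deviance summaries.

Subject random-effect draws are bulky and only needed for in-sample reuse;
``save_draws(..., include_random_effects=True)`` adds them to the draws
table.  A posterior reloaded without them supports every *cut* (new-
individual) prediction.
"""

from __future__ import annotations

import dataclasses
import json
import math
from pathlib import Path

import numpy as np
import pandas as pd

from .model import FitDiagnostics, ModelSpec, PosteriorDraws, PriorSpec

__all__ = ["save_draws", "load_draws", "save_diagnostics", "load_diagnostics"]

_EFFECTS = ("intercept", "slope", "curvature")


def save_draws(
    draws: PosteriorDraws,
    prefix: str | Path,
    diagnostics: FitDiagnostics | None = None,
    include_random_effects: bool = False,
) -> list[Path]:
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    paths = []

    table = draws.to_frame(include_random_effects=include_random_effects)
    extra = {}
    if draws.mu_alpha is not None:
        extra["mu_alpha"] = draws.mu_alpha
        extra["sigma_cond"] = draws.sigma_cond
    if extra:
        per_chain_n = draws.n_draws // draws.n_chains
        it = np.tile(np.arange(per_chain_n), draws.n_chains)
        table = pd.concat(
            [table]
            + [
                pd.DataFrame({"parameter": k, "chain": draws.chain, "iteration": it, "value": v})
                for k, v in extra.items()
            ],
            ignore_index=True,
        )
    draws_path = prefix.parent / f"{prefix.name}_draws.csv"
    table.to_csv(draws_path, index=False)
    paths.append(draws_path)

    spec = dataclasses.asdict(draws.spec)
    prior = dataclasses.asdict(draws.prior)
    if prior.get("wishart_scale") is not None:
        prior["wishart_scale"] = np.asarray(prior["wishart_scale"]).tolist()
    meta = {
        "spec": spec,
        "prior": prior,
        "n_chains": draws.n_chains,
        "n_draws": draws.n_draws,
        "subject_ids": list(draws.subject_ids) if include_random_effects else [],
    }
    meta_path = prefix.parent / f"{prefix.name}_meta.json"
    meta_path.write_text(json.dumps(meta, indent=1))
    paths.append(meta_path)

    if diagnostics is not None:
        paths.append(save_diagnostics(diagnostics, prefix))
    return paths


def save_diagnostics(diagnostics: FitDiagnostics, prefix: str | Path) -> Path:
    prefix = Path(prefix)
    path = prefix.parent / f"{prefix.name}_diagnostics.json"
    payload = {
        "rhat": diagnostics.rhat,
        "dbar": None if math.isnan(diagnostics.dbar) else diagnostics.dbar,
        "p_d": None if math.isnan(diagnostics.p_d) else diagnostics.p_d,
        "dic": None if math.isnan(diagnostics.dic) else diagnostics.dic,
    }
    path.write_text(json.dumps(payload, indent=1))
    return path


def load_diagnostics(prefix: str | Path) -> FitDiagnostics:
    prefix = Path(prefix)
    payload = json.loads((prefix.parent / f"{prefix.name}_diagnostics.json").read_text())
    return FitDiagnostics(
        rhat=payload.get("rhat", {}),
        dbar=payload["dbar"] if payload.get("dbar") is not None else math.nan,
        p_d=payload["p_d"] if payload.get("p_d") is not None else math.nan,
        dic=payload["dic"] if payload.get("dic") is not None else math.nan,
    )


def load_draws(prefix: str | Path) -> PosteriorDraws:
    """Rebuild a posterior from persisted text artifacts.

    Random-effect draws are restored when present in the table; otherwise the
    posterior carries an empty subject axis and supports cut predictions only.
    """
    prefix = Path(prefix)
    meta = json.loads((prefix.parent / f"{prefix.name}_meta.json").read_text())
    spec_kwargs = dict(meta["spec"])
    spec_kwargs["covariate_names"] = tuple(spec_kwargs.get("covariate_names", ()))
    spec = ModelSpec(**spec_kwargs)
    prior_kwargs = dict(meta["prior"])
    for tup in ("lambda_bounds", "intercept_bounds", "df_bounds"):
        prior_kwargs[tup] = tuple(prior_kwargs[tup])
    if prior_kwargs.get("wishart_scale") is not None:
        prior_kwargs["wishart_scale"] = np.asarray(prior_kwargs["wishart_scale"])
    prior = PriorSpec(**prior_kwargs)

    table = pd.read_csv(prefix.parent / f"{prefix.name}_draws.csv")
    wide = {
        name: grp.sort_values(["chain", "iteration"])["value"].to_numpy()
        for name, grp in table.groupby("parameter")
    }
    q = spec.q
    K = meta["n_draws"]
    beta = np.column_stack([wide[f"beta{k}"] for k in range(q)])
    sig = [np.asarray(wide[f"sigma{k}"]) ** 2 for k in range(q)]
    Sigma = np.zeros((K, q, q))
    for k in range(q):
        Sigma[:, k, k] = sig[k]
    for k in range(q):
        for l in range(k + 1, q):
            cov = wide[f"rho{k}{l}"] * np.sqrt(sig[k] * sig[l])
            Sigma[:, k, l] = Sigma[:, l, k] = cov
    gamma = None
    gnames = [
        f"gamma_{name}_{_EFFECTS[k]}" for name in spec.covariate_names for k in range(q)
    ]
    if gnames:
        gamma = np.column_stack([wide[g] for g in gnames])

    subject_ids = tuple(meta.get("subject_ids", ()))
    b = np.zeros((K, len(subject_ids), q), dtype=np.float32)
    for i, sid in enumerate(subject_ids):
        for k in range(q):
            b[:, i, k] = wide[f"b_{_EFFECTS[k]}[{sid}]"]

    per_chain = K // meta["n_chains"]
    return PosteriorDraws(
        spec=spec,
        prior=prior,
        subject_ids=subject_ids,
        beta=beta,
        gamma=gamma,
        Sigma=Sigma,
        sigma_w=wide["sigma_w"],
        b=b,
        nu=wide.get("nu"),
        lam=wide.get("lambda"),
        mu_alpha=wide.get("mu_alpha"),
        sigma_cond=wide.get("sigma_cond"),
        chain=np.repeat(np.arange(meta["n_chains"]), per_chain),
        n_chains=meta["n_chains"],
    )
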