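"""Default generator parameters for the five assembly-regime recipes.

These are the calibrated study conditions of the synthetic generator: each
regime's defaults are chosen so that, at the reference scale of 10 samples,
200 taxa and 1000 individuals per sample, the pipeline recovers the
regime's intended dominant process.  Traits are standardized to unit
variance across tips before filtering, so ``filter_sigma`` and
``optimum_spread`` are in trait standard-deviation units.

Fields
------
filter_sigma : float or None
    Width of the Gaussian trait filter; None disables selection
    (the sigma_f -> infinity limit).
migration : float in [0, 1]
    Weight of the shared metacommunity in each sample's sampling weights.
n_env_patches : int
    Number of distinct environmental optima (heterogeneous selection draws
    one optimum per patch, far apart on the trait axis).
optimum_spread : float
    Half-spread of patch optima on the standardized trait axis.
founder_alpha : float or None
    Shape of the per-sample multiplicative gamma lottery on local weights;
    small values concentrate each sample on a few random winners
    (ecological drift / founder effects), None disables it.
founder_keep : float or None
    Per-sample Bernoulli presence lottery: each taxon enters a sample's
    local pool with this probability.  Unlike the gamma lottery it turns
    over *membership* while keeping weights even, which is what the
    nearest-taxon turnover statistics respond to.
trait_jump : float or None
    Size (in raw trait standard deviations) of a single key-innovation
    jump added to one random clade of 15-30% of tips before filtering.
    With a narrow filter centred on the derived clade's trait mean, the
    selected pool is monophyletic, giving homogeneous selection the
    strong phylogenetic coherence a plain Brownian trait lacks.
"""

REGIME_DEFAULTS: dict[str, dict] = {
    "homogeneous_selection": dict(
        filter_sigma=0.30, migration=0.015, n_env_patches=1,
        optimum_spread=0.0, founder_alpha=None, founder_keep=0.5,
        trait_jump=5.0),
    "heterogeneous_selection": dict(
        filter_sigma=0.25, migration=0.02, n_env_patches=5,
        optimum_spread=2.0, founder_alpha=None, founder_keep=None,
        trait_jump=None),
    "dispersal_limitation": dict(
        filter_sigma=None, migration=0.30, n_env_patches=1,
        optimum_spread=0.0, founder_alpha=0.05, founder_keep=None,
        trait_jump=None),
    "homogenizing_dispersal": dict(
        filter_sigma=None, migration=1.00, n_env_patches=1,
        optimum_spread=0.0, founder_alpha=None, founder_keep=None,
        trait_jump=None),
    "neutral_drift": dict(
        filter_sigma=None, migration=0.50, n_env_patches=1,
        optimum_spread=0.0, founder_alpha=None, founder_keep=None,
        trait_jump=None),
}

REGIMES = tuple(REGIME_DEFAULTS)

# intended dominant classification per regime (neutral drift maps onto the
# residual drift/diversification category)
REGIME_TO_PROCESS = {
    "homogeneous_selection": "homogeneous_selection",
    "heterogeneous_selection": "heterogeneous_selection",
    "dispersal_limitation": "dispersal_limitation",
    "homogenizing_dispersal": "homogenizing_dispersal",
    "neutral_drift": "drift_diversification",
}
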