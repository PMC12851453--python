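"""Generate synthetic family-and-friend network populations.

Builds a binary-trait population under the additive transmission model
and a survey-like continuous population, then prints their composition.
The binary generator's ground truth is what the estimation examples try
to recover.
"""

from culttrans import (
    Biases,
    GeneratorConfig,
    generate_binary_population,
    generate_continuous_population,
)

# Binary traits under additive transmission: a student adopts the trait
# with probability other + vertical*v + horizontal*h, where v/h are the
# parental-couple and friend-pair trait indicators.
cfg = GeneratorConfig.recovery_preset(
    n_networks=1_000,
    biases={"Religiosity": Biases(vertical=0.42, horizontal=0.18, other_trait=0.10)},
    seed=11,
)
table, truth = generate_binary_population(cfg)
print(f"binary population: {table.n_networks} networks, {len(table.df)} records")
print("generating biases:", truth.biases["Religiosity"])
print("latent parental-type counts:", truth.parental_type_counts["Religiosity"])

# Continuous factor scores with survey-like ragged composition and 2%
# missingness; role-pair correlations follow configurable targets.
ccfg = GeneratorConfig.survey_preset(n_networks=500, seed=12)
ctable, ctruth = generate_continuous_population(ccfg)
roles_per_net = ctable.df.groupby("network_id")["role"].nunique()
print(f"\ncontinuous population: {ctable.n_networks} networks, "
      f"mean {roles_per_net.mean():.1f} roles per network, "
      f"{100 * ctruth.realised_missing_fraction:.1f}% scores missing")
# The parental-type counts show how many networks fall in each cell; the
# missing fraction emulates the survey's ~2% nonresponse before imputation.
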