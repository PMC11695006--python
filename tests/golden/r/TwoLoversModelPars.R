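# TwoLoversModelPars.R - parameter resolution
# Generated by the mospec Autocoder from TwoLovers.MoSpec V02.04.03
# Do not edit: regenerate from the model workbook instead.

Step <- function(x) {
  if (x >= 0) 1.0 else 0.0
}

RandUnif <- function() {
  runif(1)
}

SeedModel <- function(seed) {
  set.seed(seed)
}

CONFIGURATION_NAMES <- base::c("Default", "Decoupled", "JulietIndifferent")

ModelPars <- function(configuration = "Default") {
  if (!(configuration %in% CONFIGURATION_NAMES)) {
    stop(paste("unknown configuration:", configuration))
  }
  # free parameters: reference values
  a <- -0.2
  b <- 0.6
  c <- -0.4
  d <- -0.1
  R0 <- 1.0
  J0 <- 1.0
  if (configuration == "Decoupled") {
    a <- -1.0
    b <- 0.0
    c <- 0.0
    d <- -1.0
  }
  if (configuration == "JulietIndifferent") {
    c <- 0.0
    d <- 0.0
    J0 <- 0.0
  }
  # determined parameters, in dependency order
  CouplingGain <- b * c
  list(a = a, b = b, c = c, d = d, R0 = R0, J0 = J0, CouplingGain = CouplingGain)
}

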