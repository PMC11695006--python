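# TwoLoversModelPars.jl - parameter resolution
# Generated by the mospec Autocoder from TwoLovers.MoSpec V02.04.03
# Do not edit: regenerate from the model workbook instead.

import Random

const _unif = Random.MersenneTwister(0)

SeedModel(seed) = Random.seed!(_unif, seed)

RandUnif() = rand(_unif)

Step(x) = x >= 0.0 ? 1.0 : 0.0

const CONFIGURATION_NAMES = ["Default", "Decoupled", "JulietIndifferent"]

function ModelPars(configuration::String = "Default")
    if !(configuration in CONFIGURATION_NAMES)
        error("unknown configuration: " * configuration)
    end
    # free parameters: reference values
    a = -0.2
    b = 0.6
    c = -0.4
    d = -0.1
    R0 = 1.0
    J0 = 1.0
    if configuration == "Decoupled"
        a = -1.0
        b = 0.0
        c = 0.0
        d = -1.0
    end
    if configuration == "JulietIndifferent"
        c = 0.0
        d = 0.0
        J0 = 0.0
    end
    # determined parameters, in dependency order
    CouplingGain = b * c
    Dict{String,Float64}("a" => a, "b" => b, "c" => c, "d" => d, "R0" => R0, "J0" => J0, "CouplingGain" => CouplingGain)
end

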