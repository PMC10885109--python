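>IGHV1-64 synthetic stand-in V-region (FR1-FR3, fixed fixture layout)
EVQLVESGGGLVQPGGSLRLSCAASGYTFTSYWMHWVRQAPGKGLEWVSEINPSNGRTNYAQKFQGRFTISRDNSKNTLYLQMNSLRAEDTAVYYCAR
>IGHV5-17 synthetic stand-in V-region (FR1-FR3, fixed fixture layout)
EVQLVESGGGLVQPGGSLRLSCAASGFTFSDYGMAWVRQAPGKGLEWVSYISSGSSTIYYADTVKGRFTISRDNSKNTLYLQMNSLRAEDTAVYYCAR
>IGHV1-82 synthetic stand-in V-region (FR1-FR3, fixed fixture layout)
EVQLVESGGGLVQPGGSLRLSCAASGYTFTDYEMHWVRQAPGKGLEWVSAIDPETGGTAYNQKFKGRFTISRDNSKNTLYLQMNSLRAEDTAVYYCAR
>IGHV2-2 synthetic stand-in V-region (FR1-FR3, fixed fixture layout)
EVQLVESGGGLVQPGGSLRLSCAASGFSLTSYGVHWVRQAPGKGLEWVSVIWSGGSTDYNAAFISGRFTISRDNSKNTLYLQMNSLRAEDTAVYYCAR
>IGHV3-6 synthetic stand-in V-region (FR1-FR3, fixed fixture layout)
EVQLVESGGGLVQPGGSLRLSCAASGFTFSNYWMNWVRQAPGKGLEWVSQIRLKSDNYATHYAESGRFTISRDNSKNTLYLQMNSLRAEDTAVYYCAR
>IGHV5-9 synthetic stand-in V-region (FR1-FR3, fixed fixture layout)
EVQLVESGGGLVQPGGSLRLSCAASGFTFSSYAMSWVRQAPGKGLEWVSTISSGGSYTYYPDSVKGRFTISRDNSKNTLYLQMNSLRAEDTAVYYCAR
>IGHV9-3 synthetic stand-in V-region (FR1-FR3, fixed fixture layout)
EVQLVESGGGLVQPGGSLRLSCAASGYSITSDYAWWVRQAPGKGLEWVSYISYSGSTSYNPSLKSGRFTISRDNSKNTLYLQMNSLRAEDTAVYYCAR
>IGHV1-18 synthetic stand-in V-region (FR1-FR3, fixed fixture layout)
EVQLVESGGGLVQPGGSLRLSCAASGYTFTSYGISWVRQAPGKGLEWVSWISAYNGNTNYAQKLQGRFTISRDNSKNTLYLQMNSLRAEDTAVYYCAR
>IGHV14-3 synthetic stand-in V-region (FR1-FR3, fixed fixture layout)
EVQLVESGGGLVQPGGSLRLSCAASGYTFTRYWMHWVRQAPGKGLEWVSAIYPGNSDTSYNQKFKGRFTISRDNSKNTLYLQMNSLRAEDTAVYYCAR
>IGHV6-6 synthetic stand-in V-region (FR1-FR3, fixed fixture layout)
EVQLVESGGGLVQPGGSLRLSCAASGFTFSDAWMDWVRQAPGKGLEWVSEIRSKANNHATYYAESGRFTISRDNSKNTLYLQMNSLRAEDTAVYYCAR
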