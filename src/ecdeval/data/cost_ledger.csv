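label,category,perspective,arm,unit_cost_usd,quantity,amount_usd
Personnel: community health volunteers,personnel,provider_direct,group_only,,,3570
Personnel: community health volunteers,personnel,provider_direct,mixed,,,4230
Personnel: mentor CHVs,personnel,provider_direct,group_only,,,310
Personnel: mentor CHVs,personnel,provider_direct,mixed,,,314
Personnel: subcounty supervisors,personnel,provider_direct,group_only,,,9094
Personnel: subcounty supervisors,personnel,provider_direct,mixed,,,9153
Personnel: implementing partner staff,personnel,provider_direct,both,,,7271
Travel and accommodation,travel_accommodation,provider_direct,group_only,,,19719
Travel and accommodation,travel_accommodation,provider_direct,mixed,,,20243
Supplements and incentives,supplements_incentives,provider_direct,both,,,2729
Administrative costs,administrative,provider_indirect,both,,,3301
Start-up costs,startup,provider_indirect,both,,,1429
Mother's opportunity costs,mother_time,societal,group_only,,,7096
Mother's opportunity costs,mother_time,societal,mixed,,,8194
Venue costs,venue,societal,group_only,,,1652
Venue costs,venue,societal,mixed,,,1239
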