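region,site,start_date,end_date,duty_record_min,duty_interval_min
GOA,CB,07/13/11,02/19/12,,
GOA,CB,05/03/12,02/21/13,10,12
GOA,CB,06/06/13,09/05/13,,
GOA,CB,09/05/13,04/28/14,,
GOA,CB,04/29/14,09/09/14,,
GOA,CB,09/09/14,05/02/15,,
GOA,CB,05/01/15,09/06/15,,
GOA,CB,04/30/17,09/12/17,,
GOA,CB,09/14/17,06/16/18,,
GOA,CB,04/25/19,09/27/19,,
GOA,PT,09/09/12,06/10/13,,
GOA,PT,06/11/13,08/20/13,,
GOA,PT,09/03/13,03/21/14,,
GOA,PT,04/30/14,09/10/14,,
GOA,QN,09/11/13,04/16/14,,
GOA,QN,09/10/14,05/02/15,,
GOA,QN,05/02/15,08/18/15,,
GOA,QN,04/30/17,09/14/17,,
GOA,AB,04/28/17,09/14/17,,
GOA,KOA,04/24/19,09/27/19,,
BSAI,BD,08/27/10,05/26/11,,
BSAI,BD,05/31/11,08/11/11,5,10
BSAI,KS,06/03/10,08/26/10,,
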