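label,logit,reference_band
Breathless several days a week,-3.86,Low Impact
Breathless walking up hills,-3.72,Low Impact
Difficult to carry heavy loads; etc,-3.16,Low Impact
Have to stop/slow down if hurry/walk fast,-2.98,Low Impact
Chest condition causes a few problems,-2.91,Low Impact
Difficult to walk up hill; light gardening; etc,-2.64,Low Impact
Most days are good in average week,-2.63,Low Impact
Stops 1 or 2 things,-2.15,Low Impact
Breathless walking up a flight of stairs,-2.15,Low Impact
Cough only with chest infections,-2.06,Low Impact
Walk slower than others or stop for rests,-1.52,Low Impact
Breathless only with chest infections,-1.52,Low Impact
Get exhausted easily,-1.47,Low Impact
Walk slowly or stop walking one flight of stairs,-1.14,Low Impact
Bring up phlegm only with chest infections,-1.07,Low Impact
Usually cannot play sports or games,-1.05,Low Impact
Housework takes long or stop for rests,-0.91,Medium Impact
Breathless most days a week,-0.80,Medium Impact
Bring up phlegm several days a week,-0.77,Medium Impact
Wheezing attacks only with chest infections,-0.68,Medium Impact
Cough several days a week,-0.64,Medium Impact
Wheezing attacks a few days a month,-0.35,Medium Impact
1-2 attack of chest trouble in last year,-0.30,Medium Impact
Bring up phlegm most days a week,-0.21,Medium Impact
A few good days in an average week,-0.19,Medium Impact
Cough most days a week,-0.09,Medium Impact
Breathless when bending over,-0.07,Medium Impact
Wheeze worse in morning,-0.02,Medium Impact
Chest causes lot of problems or most important problem,0.15,High Impact
3 or more attacks of chest trouble in last year,0.20,High Impact
Get afraid/panic when can't get breath,0.21,High Impact
Breathless walking on level ground outside the house,0.32,High Impact
Wheezing attacks several days a week,0.36,High Impact
Cough and/or breathing embarrassing in public,0.47,High Impact
Cough and/or breathing disturbs sleep,0.49,High Impact
Feel not in control of chest problem,0.49,High Impact
Wheezing attacks most days a week,0.58,High Impact
Stops patient doing most things they want to do,0.60,High Impact
Breathless getting washed/dressed,0.62,High Impact
No good days in average week,0.63,High Impact
Breathless when talking,0.81,High Impact
Exercise felt not to be safe,0.92,High Impact
Everything seems too much of an effort,0.92,High Impact
Cough causes tiredness,1.13,Very High Impact
Takes a long time to get washed or dressed,1.24,Very High Impact
Breathless walking around home,1.47,Very High Impact
Chest trouble is a nuisance to family; friends,1.49,Very High Impact
Cannot take bath/shower or takes long time,1.55,Very High Impact
Cannot go out for entertainment,1.87,Very High Impact
Coughs hurts,2.11,Very High Impact
Cannot do housework,2.20,Very High Impact
Have become frail or invalid because of chest,2.42,Very High Impact
Cannot go out of house for shopping,2.69,Very High Impact
Stops patient doing everything they want to do,3.11,Very High Impact
Cannot move far from bed or chair,3.40,Very High Impact
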