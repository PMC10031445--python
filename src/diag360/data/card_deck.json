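{
  "schema_id": "diag360.card_deck",
  "schema_version": 1,
  "cards": [
    {
      "index": 1,
      "title": "title page",
      "kind": "front_matter",
      "goal": "",
      "parts": [],
      "examples": []
    },
    {
      "index": 2,
      "title": "content",
      "kind": "front_matter",
      "goal": "",
      "parts": [
        "MI basic attitude and core skills",
        "Five diabetes coaching steps from agenda to rounding up"
      ],
      "examples": []
    },
    {
      "index": 3,
      "title": "MI basic attitude",
      "kind": "mi_skill",
      "goal": "Adopt a collaborative, accepting, and compassionate stance that evokes the patient's own motivation.",
      "parts": ["Partnership", "Acceptance", "Compassion", "Evocation"],
      "examples": [
        "\"You know your own situation best; let us look at it together.\""
      ]
    },
    {
      "index": 4,
      "title": "MI core skills 1",
      "kind": "mi_skill",
      "goal": "Use open questions to invite the patient to tell their own story.",
      "parts": ["Open questions", "Avoiding closed yes/no questions"],
      "examples": [
        "\"What would you most like to change about your health?\""
      ]
    },
    {
      "index": 5,
      "title": "MI core skills 2",
      "kind": "mi_skill",
      "goal": "Affirm strengths and reflect what the patient says to show understanding.",
      "parts": ["Affirmations", "Simple and complex reflections"],
      "examples": [
        "\"You have already managed to walk three times a week; that takes persistence.\""
      ]
    },
    {
      "index": 6,
      "title": "MI core skills 3",
      "kind": "mi_skill",
      "goal": "Summarize and exchange information with permission.",
      "parts": ["Summaries", "Ask-offer-ask information exchange"],
      "examples": [
        "\"May I share what the profile wheel shows about your blood pressure?\""
      ]
    },
    {
      "index": 7,
      "title": "diabetes coaching steps overview",
      "kind": "front_matter",
      "goal": "",
      "parts": [
        "Step 1 agenda",
        "Step 2 current situation",
        "Step 3 motivation",
        "Step 4 planning",
        "Step 5 rounding up"
      ],
      "examples": []
    },
    {
      "index": 8,
      "title": "step 1 agenda",
      "kind": "step",
      "step_number": 1,
      "goal": "Set the agenda together using the profile wheel's orange and red parameters.",
      "parts": [
        "Review the profile wheel together",
        "List the orange and red parameters",
        "Let the patient choose what to discuss first"
      ],
      "examples": [
        "\"Which of these results would you like to talk about today?\""
      ]
    },
    {
      "index": 9,
      "title": "step 2 current situation I",
      "kind": "step",
      "step_number": 2,
      "goal": "Explore how the chosen parameter plays out in the patient's daily life.",
      "parts": ["Open exploration of the current situation", "Reflective listening"],
      "examples": [
        "\"Tell me about a typical day; where does this issue show up?\""
      ]
    },
    {
      "index": 10,
      "title": "step 2 current situation II",
      "kind": "step",
      "step_number": 2,
      "goal": "Deepen understanding of context, earlier attempts, and barriers.",
      "parts": ["Earlier change attempts", "Barriers and supports"],
      "examples": [
        "\"What have you tried before, and what got in the way?\""
      ]
    },
    {
      "index": 11,
      "title": "step 3 motivation I",
      "kind": "step",
      "step_number": 3,
      "goal": "Elicit the patient's own reasons for change.",
      "parts": ["Evoking change talk", "Exploring values"],
      "examples": [
        "\"Why would improving this matter to you personally?\""
      ]
    },
    {
      "index": 12,
      "title": "step 3 motivation II",
      "kind": "step",
      "step_number": 3,
      "goal": "Gauge and strengthen confidence and importance.",
      "parts": ["Importance ruler", "Confidence ruler"],
      "examples": [
        "\"On a scale from 0 to 10, how confident are you that you could do this?\""
      ]
    },
    {
      "index": 13,
      "title": "step 4 planning I",
      "kind": "step",
      "step_number": 4,
      "goal": "Translate motivation into a concrete, patient-owned goal.",
      "parts": ["Goal setting", "Choosing among intervention options"],
      "examples": [
        "\"Which of these options feels like the best fit for you?\""
      ]
    },
    {
      "index": 14,
      "title": "step 4 planning II",
      "kind": "step",
      "step_number": 4,
      "goal": "Make the plan specific and anticipate obstacles.",
      "parts": ["When-where-how planning", "If-then coping plans"],
      "examples": [
        "\"If it rains on your walking day, what will you do instead?\""
      ]
    },
    {
      "index": 15,
      "title": "step 5 rounding up",
      "kind": "step",
      "step_number": 5,
      "goal": "Choose an intervention for one orange or red parameter and summarize the plan.",
      "parts": [
        "Choose the intervention",
        "Summarize",
        "Confirm follow-up in about 3 months"
      ],
      "examples": [
        "\"To sum up: you will join the walking club to improve your activity score; your neighbor will join you as backup.\""
      ],
      "summary_fields": [
        "current_situation",
        "goal_parameter",
        "chosen_intervention",
        "backup_plans",
        "resources"
      ]
    }
  ]
}
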